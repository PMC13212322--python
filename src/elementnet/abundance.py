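"""Abundance normalization, transforms and dissimilarities.

Gene abundances are carried as pandas DataFrames with genes as rows and
samples as columns; per-sample metadata (site, depth in cmbsf) rides along
in an :class:`AbundanceTable`.

RPM (reads per million) is the length-normalized relative abundance
``10^6 * (count/length) / sum_g(count/length)`` per sample, identical in
form to TPM.  Downstream rank correlations are invariant to any monotone
per-sample rescaling, so RPM vs raw rates is consequence-free for network
edges, but RPM is what gets written to disk and plotted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger(__name__)

RPM_SCALE = 1.0e6


@dataclass
class AbundanceTable:
    """Gene x sample abundance matrix plus per-sample metadata.

    ``values``: DataFrame indexed by gene_id, columns are sample ids.
    ``sample_meta``: DataFrame indexed by sample id with at least columns
    ``site`` and ``depth_cmbsf`` (may be empty for transform-only use).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene_ids in abundance table")
        if not self.sample_meta.empty:
            missing = [s for s in self.values.columns if s not in self.sample_meta.index]
            if missing:
                raise ValueError(f"samples missing from metadata: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def depths(self) -> np.ndarray:
        return self.sample_meta.loc[self.values.columns, "depth_cmbsf"].to_numpy(float)

    def subset_samples(self, samples) -> "AbundanceTable":
        meta = self.sample_meta.loc[list(samples)] if not self.sample_meta.empty else self.sample_meta
        return AbundanceTable(self.values[list(samples)], meta)

    def subset_genes(self, genes) -> "AbundanceTable":
        return AbundanceTable(self.values.loc[list(genes)], self.sample_meta)


@dataclass
class DissimilarityMatrix:
    """Symmetric sample x sample dissimilarity matrix with labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("dissimilarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("dissimilarity matrix has nonzero diagonal")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def compute_rpm(counts: pd.DataFrame, lengths: pd.Series, sample_meta: pd.DataFrame | None = None) -> AbundanceTable:
    """Length-normalize mapped-read counts to RPM.

    Per sample: ``rate_g = count_g / length_g``;
    ``RPM_g = 10^6 * rate_g / sum_g(rate_g)``.  Column sums are 10^6.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"genes without length: {missing[:5]}")
    bad = lengths[lengths <= 0]
    if len(bad):
        raise ValueError(f"non-positive gene length for gene {bad.index[0]!r}")
    rates = counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero counts; cannot normalize")
    rpm = rates.div(totals, axis=1) * RPM_SCALE
    meta = sample_meta if sample_meta is not None else pd.DataFrame()
    return AbundanceTable(rpm, meta)


def log1p_transform(table: AbundanceTable) -> AbundanceTable:
    """Elementwise log(1+x); monotone and zero-preserving."""
    if (table.values.to_numpy() < 0).any():
        raise ValueError("negative abundance passed to log1p_transform")
    return replace(table, values=np.log1p(table.values))


def hellinger_transform(table: AbundanceTable) -> AbundanceTable:
    """Per sample: sqrt(x_g / sum_g x_g).  Transformed columns have unit
    Euclidean norm, which tempers the influence of dominant genes in
    downstream Bray-Curtis / ordination analyses."""
    vals = table.values
    if (vals.to_numpy() < 0).any():
        raise ValueError("negative abundance passed to hellinger_transform")
    totals = vals.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} is all-zero; Hellinger undefined")
    return replace(table, values=np.sqrt(vals.div(totals, axis=1)))


def bray_curtis(table: AbundanceTable) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples:
    ``BC(x, y) = sum|x_g - y_g| / sum(x_g + y_g)``, in [0, 1]."""
    vals = table.values.to_numpy(float).T  # samples x genes
    if (vals < 0).any():
        raise ValueError("negative abundance passed to bray_curtis")
    zero_samples = np.where(vals.sum(axis=1) == 0)[0]
    if len(zero_samples) >= 2:
        names = [table.sample_ids[i] for i in zero_samples]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample pair: {names}")
    d = squareform(pdist(vals, metric="braycurtis"))
    return DissimilarityMatrix(table.sample_ids, d)


def aggregate_by_group(
    table: AbundanceTable,
    gene_to_group: pd.Series | dict,
    relative: bool = False,
) -> AbundanceTable:
    """Sum member-gene abundances per group (e.g. taxon order, pathway).

    Genes absent from the map are assigned ``"Unclassified"``.  With
    ``relative=True``, columns are rescaled to sum to 1 over the groups of
    the *provided* (possibly subset) table.
    """
    mapping = pd.Series(gene_to_group)
    if mapping.empty:
        raise ValueError("empty gene -> group map")
    groups = mapping.reindex(table.values.index).fillna("Unclassified")
    agg = table.values.groupby(groups).sum()
    agg = agg.sort_index()
    if relative:
        totals = agg.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"sample {zero.index[0]!r} has zero total; cannot convert to relative abundance")
        agg = agg.div(totals, axis=1)
    return AbundanceTable(agg, table.sample_meta)


def drop_zero_variance_genes(table: AbundanceTable) -> AbundanceTable:
    """Drop genes constant across all samples (ranks undefined downstream)."""
    vals = table.values
    keep = vals.nunique(axis=1) > 1
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropping %d zero-variance gene(s) before correlation", dropped)
    return replace(table, values=vals.loc[keep])
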