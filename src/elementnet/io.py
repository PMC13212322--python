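"""Tab-separated readers/writers and network export.

All tables are TSV with genes as rows (first column ``gene_id``) and
samples as columns; dissimilarity matrices are square labelled TSV;
networks are additionally exported as GraphML.  Writers use a fixed float
format so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from elementnet.abundance import AbundanceTable, DissimilarityMatrix
from elementnet.synth import GroundTruth

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)
    return path


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> Path:
    return write_tsv(counts, path, index_label="gene_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> Path:
    return write_tsv(annotation, path, index_label="gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_samples(sample_meta: pd.DataFrame, path: str | Path) -> Path:
    return write_tsv(sample_meta, path, index_label="sample_id")


def write_abundance(table: AbundanceTable, path: str | Path) -> Path:
    return write_tsv(table.values, path, index_label="gene_id")


def read_abundance(values_path: str | Path, samples_path: str | Path | None = None) -> AbundanceTable:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = read_samples(samples_path) if samples_path else pd.DataFrame()
    return AbundanceTable(values, meta)


def write_dissimilarity(d: DissimilarityMatrix, path: str | Path) -> Path:
    return write_tsv(d.to_frame(), path, index_label="sample_id")


def read_dissimilarity(path: str | Path) -> DissimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DissimilarityMatrix(list(df.index), df.to_numpy(float))


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    paths = [
        write_tsv(truth.planted_edges, out_dir / "truth_planted_edges.tsv", index_label="idx"),
        write_tsv(truth.trend_genes, out_dir / "truth_trend_genes.tsv", index_label="gene_id"),
        write_tsv(truth.block_membership.rename("block").to_frame(), out_dir / "truth_block_membership.tsv",
                  index_label="gene_id"),
    ]
    return paths


def write_edges(net, path: str | Path) -> Path:
    """Edge list TSV: fe_gene, target_gene, rho, p, q, sign."""
    edges = net.edges.copy()
    if "sign" not in edges.columns and len(edges):
        edges["sign"] = np.sign(edges["rho"]).astype(int)
    cols = [c for c in ("fe_gene", "target_gene", "rho", "p", "q", "sign") if c in edges.columns]
    edges = edges[cols] if len(edges) else pd.DataFrame(columns=cols)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    edges.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=False)
    return path


def write_graphml(net, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.graph if hasattr(net, "graph") else net, path)
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
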