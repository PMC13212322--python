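import numpy as np
import pandas as pd
import pytest

from elementnet.abundance import AbundanceTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def make_table(values, gene_ids=None, sites=None, depths=None):
    """Build an AbundanceTable from a 2-D array (genes x samples)."""
    values = np.asarray(values, float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "site": sites or ["A"] * n_samples,
            "depth_cmbsf": depths if depths is not None else np.arange(2.0, 2.0 + 4 * n_samples, 4.0),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return AbundanceTable(pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples), meta)


def make_annotation(gene_cycles, taxa=None, lengths=None):
    """Annotation frame from {gene_id: cycle}."""
    genes = list(gene_cycles)
    return pd.DataFrame(
        {
            "cycle": [gene_cycles[g] for g in genes],
            "category": ["cat"] * len(genes),
            "taxon": taxa or ["TaxonA"] * len(genes),
            "length_bp": lengths or [1000] * len(genes),
        },
        index=pd.Index(genes, name="gene_id"),
    )
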