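import numpy as np
import pandas as pd
import pytest

from sarcnv.cnv_profile import DiscreteCNVMatrix, QuantileThresholds
from sarcnv.genomic_data import GeneCNVMatrix, GeneModel, GenomicInterval


def make_genes(n, chrom="1", start=1000, length=100, spacing=1000, bands=None):
    genes = []
    for i in range(n):
        lo = start + i * spacing
        band = None if bands is None else bands[i]
        genes.append(GeneModel(f"g{i}", GenomicInterval(chrom, lo, lo + length), band=band))
    return genes


def make_matrix(values, cohort="TEST", bands=None):
    """Continuous gene-level matrix from a 2-D array (rows = genes)."""
    values = np.asarray(values, dtype=float)
    genes = make_genes(values.shape[0], bands=bands)
    df = pd.DataFrame(
        values,
        index=[g.symbol for g in genes],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return GeneCNVMatrix(genes=genes, values=df, cohort_label=cohort)


def make_discrete(codes, cohort="TEST", bands=None):
    """Discrete code matrix from a 2-D array of {-2..2, nan}."""
    codes = np.asarray(codes, dtype=float)
    genes = make_genes(codes.shape[0], bands=bands)
    df = pd.DataFrame(
        codes,
        index=[g.symbol for g in genes],
        columns=[f"s{j}" for j in range(codes.shape[1])],
    )
    return DiscreteCNVMatrix(
        genes=genes, values=df,
        thresholds=QuantileThresholds(-2.0, -1.0, 1.0, 2.0), cohort_label=cohort,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
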