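"""Quantile discretization and amplification/deletion frequency profiling.

Continuous gene-level log2 ratios are discretized into five copy-number
levels using platform-wide quantiles of the pooled gene x sample
distribution: values above the 95th percentile are significant
amplifications (+2), values in the 85th-95th band are amplifications (+1),
values below the 5th percentile are significant deletions (-2), values in
the 5th-15th band are deletions (-1), and everything between the 15th and
85th percentiles is unchanged (0). Thresholds are computed per
cohort/platform and never shared across cohorts, because each array
platform has its own intensity scale.

Gain calls are codes {+1, +2} and loss calls {-1, -2}; per-gene frequencies
divide call counts by the number of non-missing samples for that gene, and
band frequencies divide total member-gene calls by the summed per-gene
sample counts. A healthy-population background (DGV-style records) is
summarized per gene by distinct-individual counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genomic_data import (
    GeneCNVMatrix,
    GeneModel,
    HealthyVariantRecord,
    _trees_by_chrom,
)

logger = logging.getLogger(__name__)

FREQUENCY_COLUMNS = [
    "unit", "unit_kind", "cohort", "amp_freq", "del_freq",
    "n_samples", "n_genes_in_band",
]


@dataclass(frozen=True)
class QuantileThresholds:
    """5th/15th/85th/95th percentiles of one platform's pooled distribution."""

    p05: float
    p15: float
    p85: float
    p95: float

    def __post_init__(self) -> None:
        if not (self.p05 <= self.p15 <= self.p85 <= self.p95):
            raise ValueError("thresholds must satisfy p05 <= p15 <= p85 <= p95")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p05, self.p15, self.p85, self.p95)


@dataclass
class DiscreteCNVMatrix:
    """Genes x samples codes in {-2,-1,0,1,2} (NaN = missing)."""

    genes: list[GeneModel]
    values: pd.DataFrame
    thresholds: QuantileThresholds
    cohort_label: str = ""

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        observed = arr[np.isfinite(arr)]
        if not np.isin(observed, (-2.0, -1.0, 0.0, 1.0, 2.0)).all():
            raise ValueError("discrete matrix entries must be in {-2,-1,0,1,2}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _pooled_values(matrix) -> np.ndarray:
    if isinstance(matrix, (GeneCNVMatrix, DiscreteCNVMatrix)):
        arr = matrix.values.to_numpy(dtype=float)
    elif isinstance(matrix, pd.DataFrame):
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
    return arr[np.isfinite(arr)]


def compute_thresholds(matrix) -> QuantileThresholds:
    """Pooled 5/15/85/95th percentiles (type-7 linear interpolation)."""
    pooled = _pooled_values(matrix)
    if pooled.size == 0:
        raise ValueError("cannot compute thresholds: no non-missing values")
    q = np.quantile(pooled, [0.05, 0.15, 0.85, 0.95], method="linear")
    return QuantileThresholds(*(float(v) for v in q))


def discretize_values(values: np.ndarray, thresholds: QuantileThresholds) -> np.ndarray:
    """Apply the five-level coding rule elementwise; NaN stays NaN.

    Boundary ties resolve toward the milder code: ``v == p95`` codes +1 and
    ``v == p85`` codes 0 (mirrored on the deletion side).
    """
    v = np.asarray(values, dtype=float)
    codes = np.full(v.shape, np.nan)
    finite = np.isfinite(v)
    t = thresholds
    codes[finite & (v > t.p95)] = 2.0
    codes[finite & (v > t.p85) & (v <= t.p95)] = 1.0
    codes[finite & (v < t.p05)] = -2.0
    codes[finite & (v >= t.p05) & (v < t.p15)] = -1.0
    codes[finite & np.isnan(codes)] = 0.0
    return codes


def discretize(matrix: GeneCNVMatrix, thresholds: QuantileThresholds) -> DiscreteCNVMatrix:
    codes = discretize_values(matrix.values.to_numpy(dtype=float), thresholds)
    df = pd.DataFrame(codes, index=matrix.values.index, columns=matrix.values.columns)
    return DiscreteCNVMatrix(
        genes=list(matrix.genes), values=df, thresholds=thresholds,
        cohort_label=matrix.cohort_label,
    )


class CNVQuantileDiscretizer(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer for the five-level quantile coding.

    ``fit`` pools all finite entries of ``X`` (array or DataFrame, any
    orientation) and stores the platform thresholds in ``thresholds_``;
    ``transform`` maps values to codes in {-2,-1,0,1,2}, preserving NaN.
    """

    def fit(self, X, y=None):
        self.thresholds_ = compute_thresholds(X)
        return self

    def transform(self, X):
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("CNVQuantileDiscretizer must be fitted before transform")
        if isinstance(X, pd.DataFrame):
            codes = discretize_values(X.to_numpy(dtype=float), self.thresholds_)
            return pd.DataFrame(codes, index=X.index, columns=X.columns)
        return discretize_values(np.asarray(X, dtype=float), self.thresholds_)


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def gene_frequencies(dmatrix: DiscreteCNVMatrix, cohort: Optional[str] = None) -> pd.DataFrame:
    """Per-gene amplification/deletion frequencies.

    amp_freq = (# codes in {1,2}) / (# non-missing samples for the gene),
    del_freq analogous with {-1,-2}. Genes with zero non-missing samples are
    omitted with a warning.
    """
    cohort = dmatrix.cohort_label if cohort is None else cohort
    codes = dmatrix.values.to_numpy(dtype=float)
    finite = np.isfinite(codes)
    n = finite.sum(axis=1)
    gains = (finite & (codes >= 1)).sum(axis=1)
    losses = (finite & (codes <= -1)).sum(axis=1)
    omitted = int((n == 0).sum())
    if omitted:
        logger.warning("gene_frequencies: omitted %d genes with no observations", omitted)
    keep = n > 0
    return pd.DataFrame(
        {
            "unit": dmatrix.values.index.to_numpy()[keep],
            "unit_kind": "gene",
            "cohort": cohort,
            "amp_freq": gains[keep] / n[keep],
            "del_freq": losses[keep] / n[keep],
            "n_samples": n[keep].astype(int),
            "n_genes_in_band": 1,
        }
    )


def band_frequencies(dmatrix: DiscreteCNVMatrix, cohort: Optional[str] = None) -> pd.DataFrame:
    """Per-band frequencies over all member genes and samples.

    The denominator is the summed per-gene non-missing sample count over the
    band's member genes (equal to samples x genes with complete data, in
    which case the band frequency is exactly the mean of member-gene
    frequencies). Genes without a band label are skipped with a warning.
    """
    cohort = dmatrix.cohort_label if cohort is None else cohort
    codes = dmatrix.values.to_numpy(dtype=float)
    finite = np.isfinite(codes)
    n_samples = dmatrix.values.shape[1]

    bands: dict[str, list[int]] = {}
    unlabeled = 0
    for i, gene in enumerate(dmatrix.genes):
        if gene.band is None or gene.band == "":
            unlabeled += 1
            continue
        bands.setdefault(gene.band, []).append(i)
    if unlabeled:
        logger.warning("band_frequencies: skipped %d genes without band labels", unlabeled)

    rows = []
    for band, idx in bands.items():
        sub = codes[idx]
        subfin = finite[idx]
        denom = int(subfin.sum())
        if denom == 0:
            continue
        rows.append(
            {
                "unit": band,
                "unit_kind": "band",
                "cohort": cohort,
                "amp_freq": float((subfin & (sub >= 1)).sum() / denom),
                "del_freq": float((subfin & (sub <= -1)).sum() / denom),
                "n_samples": n_samples,
                "n_genes_in_band": len(idx),
            }
        )
    return pd.DataFrame(rows, columns=FREQUENCY_COLUMNS)


def healthy_background_frequencies(
    records: Sequence[HealthyVariantRecord],
    genes: Sequence[GeneModel],
    n_individuals: int,
) -> pd.DataFrame:
    """Per-gene background frequencies from healthy-population variants.

    amp_freq = (# distinct individuals with >= 1 gain record overlapping the
    gene) / ``n_individuals``; del_freq analogous with loss records. The
    cohort label is ``HEALTHY``.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be >= 1")
    trees = _trees_by_chrom(
        [(i, g) for i, g in enumerate(genes)], lambda pair: pair[1].interval
    )
    gain_sets: list[set[str]] = [set() for _ in genes]
    loss_sets: list[set[str]] = [set() for _ in genes]
    for rec in records:
        tree = trees.get(rec.interval.chrom)
        if tree is None:
            continue
        for hit in tree[rec.interval.start: rec.interval.end]:
            gi, gene = hit.data
            if gene.interval.overlap_length(rec.interval) > 0:
                target = gain_sets if rec.variant_class == "gain" else loss_sets
                target[gi].add(rec.individual_id)
    return pd.DataFrame(
        {
            "unit": [g.symbol for g in genes],
            "unit_kind": "gene",
            "cohort": "HEALTHY",
            "amp_freq": [len(s) / n_individuals for s in gain_sets],
            "del_freq": [len(s) / n_individuals for s in loss_sets],
            "n_samples": n_individuals,
            "n_genes_in_band": 1,
        }
    )


# ---------------------------------------------------------------------------
# Cross-cohort and tumor-vs-cell-line comparison
# ---------------------------------------------------------------------------

@dataclass
class CohortOverlap:
    """Side-by-side frequency table plus the shared recurrent gene set."""

    table: pd.DataFrame
    overlap_genes: list[str]

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_genes)


def compare_cohorts(
    tables: Sequence[pd.DataFrame], min_alteration_freq: float = 0.0
) -> CohortOverlap:
    """Align gene-level frequency tables from >= 2 cohorts.

    Returns per-gene amp/del frequencies side by side (genes present in all
    cohorts) and the set of genes whose alteration frequency
    ``max(amp_freq, del_freq)`` reaches ``min_alteration_freq`` in every
    cohort simultaneously.
    """
    if len(tables) < 2:
        raise ValueError("compare_cohorts requires >= 2 cohorts")
    pivots = []
    cohorts = []
    for t in tables:
        gene_rows = t[t["unit_kind"] == "gene"] if "unit_kind" in t.columns else t
        cohort = str(gene_rows["cohort"].iloc[0]) if len(gene_rows) else "?"
        cohorts.append(cohort)
        p = gene_rows.set_index("unit")[["amp_freq", "del_freq"]]
        p.columns = pd.MultiIndex.from_product([[cohort], p.columns])
        pivots.append(p)
    common = pivots[0].index
    for p in pivots[1:]:
        common = common.intersection(p.index)
    if len(common) == 0:
        logger.warning("compare_cohorts: cohorts share no genes")
        empty = pd.concat(pivots, axis=1, join="inner")
        return CohortOverlap(table=empty, overlap_genes=[])
    wide = pd.concat([p.loc[common] for p in pivots], axis=1)
    passing = np.ones(len(common), dtype=bool)
    for cohort in cohorts:
        alt = np.maximum(
            wide[(cohort, "amp_freq")].to_numpy(), wide[(cohort, "del_freq")].to_numpy()
        )
        passing &= alt >= min_alteration_freq
    return CohortOverlap(table=wide, overlap_genes=list(common[passing]))


def tumor_vs_cellline_table(
    tumor_tables: Sequence[pd.DataFrame],
    cellline_dmatrix: DiscreteCNVMatrix,
    panel: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Panel genes' cell-line frequencies next to each tumor cohort's.

    ``panel`` defaults to the packaged recurrent-gene panel. Genes absent
    from a cohort (or from the cell-line matrix) get missing frequencies.
    One row per panel gene.
    """
    if panel is None:
        from .synthetic_data import load_gene_panel_fixture

        panel = list(load_gene_panel_fixture()["gene"])
    panel = list(panel)
    cl = gene_frequencies(cellline_dmatrix, cohort="CELLLINE").set_index("unit")
    out = pd.DataFrame(index=pd.Index(panel, name="unit"))
    out["cellline_amp_freq"] = cl["amp_freq"].reindex(panel)
    out["cellline_del_freq"] = cl["del_freq"].reindex(panel)
    for t in tumor_tables:
        gene_rows = (t[t["unit_kind"] == "gene"] if "unit_kind" in t.columns else t)
        cohort = str(gene_rows["cohort"].iloc[0]) if len(gene_rows) else "?"
        indexed = gene_rows.set_index("unit")
        out[f"{cohort}_amp_freq"] = indexed["amp_freq"].reindex(panel)
        out[f"{cohort}_del_freq"] = indexed["del_freq"].reindex(panel)
    return out.reset_index()


def write_frequency_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
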