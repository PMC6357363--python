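"""CNV-drug response correlation and biomarker calling.

For each (gene, drug) pair, the continuous gene-level copy-number value is
correlated (Pearson) against the drug's AUC across the cell lines shared by
the CNV matrix and the AUC table. Amplification that tracks with a lower
AUC (growth inhibited at lower exposure) gives a negative r and marks a
*sensitive* biomarker; a positive r past the threshold marks a
*non-sensitive* (resistance) biomarker:

    sensitive      iff  r < -0.35 and p < 0.05
    non_sensitive  iff  r >  0.35 and p < 0.05
    none           otherwise

The two-sided p-value comes from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees
of freedom. Calls use raw p-values; Benjamini-Hochberg q-values are
reported alongside for transparency but do not enter the calling rule.
Cell-line names are matched case-insensitively with punctuation stripped
("SK-ES-1" == "SKES1") to absorb naming drift between CNV and screening
resources.
"""

from __future__ import annotations

import logging
import re
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_data import GeneCNVMatrix

logger = logging.getLogger(__name__)

R_CUT_DEFAULT = 0.35
P_CUT_DEFAULT = 0.05

CALL_ORDER = {"sensitive": 0, "non_sensitive": 1, "none": 2}


def normalize_cellline_name(name: str) -> str:
    """Uppercase and strip every non-alphanumeric character."""
    return re.sub(r"[^0-9A-Za-z]", "", str(name)).upper()


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson r with a two-sided t-based p-value.

    Requires n >= 3 complete pairs and non-constant inputs; |r| = 1 gives
    p = 0 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(x.size)
    if n < 3:
        raise ValueError("insufficient pairs: need n >= 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: zero variance in x or y")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return r, p, n


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def classify(r: float, p: float, r_cut: float = R_CUT_DEFAULT,
             p_cut: float = P_CUT_DEFAULT) -> str:
    if p < p_cut and r < -r_cut:
        return "sensitive"
    if p < p_cut and r > r_cut:
        return "non_sensitive"
    return "none"


def call_biomarkers(
    gene_matrix: GeneCNVMatrix,
    auc_table: pd.DataFrame,
    r_cut: float = R_CUT_DEFAULT,
    p_cut: float = P_CUT_DEFAULT,
) -> pd.DataFrame:
    """Correlate every gene's CNV with every drug's AUC and call biomarkers.

    ``auc_table`` is long format with columns cell_line, drug, auc. Pairs
    with fewer than 3 shared cell lines, or a constant CNV or AUC vector,
    are skipped; an error is raised only if no pair at all is testable.
    Output columns: gene, drug, r, p, q, n, call, sorted by call class then
    |r| descending.
    """
    values = gene_matrix.values
    norm_cols = {normalize_cellline_name(c): c for c in values.columns}

    rows = []
    for drug, grp in auc_table.groupby("drug", sort=True):
        shared = []
        for cell, auc in zip(grp["cell_line"], grp["auc"]):
            col = norm_cols.get(normalize_cellline_name(cell))
            if col is not None:
                shared.append((col, float(auc)))
        if len(shared) < 3:
            continue
        cols = [c for c, _ in shared]
        aucs = np.array([a for _, a in shared])
        sub = values[cols].to_numpy(dtype=float)
        for gi, gene in enumerate(values.index):
            x = sub[gi]
            mask = np.isfinite(x) & np.isfinite(aucs)
            if mask.sum() < 3:
                continue
            if np.ptp(x[mask]) == 0 or np.ptp(aucs[mask]) == 0:
                continue
            r, p, n = pearson_with_p(x[mask], aucs[mask])
            rows.append({"gene": gene, "drug": drug, "r": r, "p": p, "n": n})
    if not rows:
        raise ValueError("no (gene, drug) pair with >= 3 shared cell lines")
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["call"] = [classify(r, p, r_cut, p_cut) for r, p in zip(out["r"], out["p"])]
    out["_rank"] = out["call"].map(CALL_ORDER)
    out = out.sort_values(
        by=["_rank", "r"], key=lambda s: s.abs() if s.name == "r" else s,
        ascending=[True, False], kind="stable",
    ).drop(columns="_rank")
    return out[["gene", "drug", "r", "p", "q", "n", "call"]].reset_index(drop=True)


def write_biomarker_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
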