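"""Monotone dose-response fitting and area-under-curve drug sensitivity.

Viability is modeled as a nonincreasing function of log2 drug
concentration: a higher dose must show at least the efficacy (growth
inhibition) of a lower dose. The fit is the exact least-squares projection
of the observed viabilities onto the nonincreasing cone (isotonic
regression, pool-adjacent-violators), and the drug-sensitivity summary is
the trapezoidal area under the fitted curve over the tested
log2-concentration window. Lower AUC means greater sensitivity.

Viabilities above 1 are retained (they occur in real screens when treated
wells outgrow controls); negative viabilities are clipped to 0 with a
warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

MIN_POINTS = 4


def monotone_decreasing_fit(values: Sequence[float]) -> np.ndarray:
    """L2 projection of a sequence onto the nonincreasing cone (PAVA).

    Equal weights; the output has the same length as the input and equals
    the input whenever the input is already nonincreasing.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("expected a nonempty 1-D sequence")
    if np.all(np.diff(v) <= 0):
        return v.copy()  # feasible input is its own projection, exactly
    iso = IsotonicRegression(increasing=False)
    return iso.fit_transform(np.arange(v.size), v)


@dataclass
class DoseResponseCurve:
    """One (cell line, drug) viability series over increasing log2 doses."""

    cell_line: str
    drug: str
    log2_conc: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        self.log2_conc = np.asarray(self.log2_conc, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.log2_conc.shape != self.viability.shape:
            raise ValueError("log2_conc and viability must align")
        if self.log2_conc.size < MIN_POINTS:
            raise ValueError(f"dose-response curve needs >= {MIN_POINTS} points")
        if not np.all(np.diff(self.log2_conc) > 0):
            raise ValueError("log2 concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viabilities must be finite")
        if (self.viability < 0).any():
            logger.warning(
                "curve (%s, %s): clipped %d negative viabilities to 0",
                self.cell_line, self.drug, int((self.viability < 0).sum()),
            )
            self.viability = np.clip(self.viability, 0.0, None)

    @property
    def span(self) -> float:
        return float(self.log2_conc[-1] - self.log2_conc[0])


@dataclass(frozen=True)
class AUCRecord:
    """Area under the fitted viability curve over the tested window."""

    cell_line: str
    drug: str
    auc: float
    span: float


def fit_monotone_curve(curve: DoseResponseCurve) -> np.ndarray:
    """Nonincreasing least-squares fit of a curve's viabilities."""
    return monotone_decreasing_fit(curve.viability)


def compute_auc(
    curve: DoseResponseCurve,
    fitted: Optional[np.ndarray] = None,
    normalized: bool = False,
) -> AUCRecord:
    """Trapezoidal integral of the (fitted) viability over the log2 window.

    ``normalized=True`` divides by the window span, yielding a mean fitted
    viability instead of an area.
    """
    if fitted is None:
        fitted = fit_monotone_curve(curve)
    fitted = np.asarray(fitted, dtype=float)
    if fitted.shape != curve.log2_conc.shape:
        raise ValueError("fitted values must align with the curve's points")
    auc = float(np.trapezoid(fitted, curve.log2_conc))
    if normalized:
        auc /= curve.span
    return AUCRecord(curve.cell_line, curve.drug, auc, curve.span)


def read_dose_response(path: str | Path) -> list[DoseResponseCurve]:
    """Read a TSV with columns cell_line, drug, concentration, viability.

    Concentrations are in linear units and converted to log2; replicate
    rows at the same concentration are averaged.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_line", "drug", "concentration", "viability"):
        if col not in df.columns:
            raise ValueError(f"dose-response file {path} is missing column {col!r}")
    if (df["concentration"] <= 0).any():
        raise ValueError("concentrations must be positive (linear units)")
    curves = []
    for (cell, drug), grp in df.groupby(["cell_line", "drug"], sort=True):
        pooled = grp.groupby("concentration", sort=True)["viability"].mean()
        curves.append(
            DoseResponseCurve(
                cell_line=str(cell), drug=str(drug),
                log2_conc=np.log2(pooled.index.to_numpy(dtype=float)),
                viability=pooled.to_numpy(dtype=float),
            )
        )
    return curves


def auc_table(curves: Iterable[DoseResponseCurve], normalized: bool = False) -> pd.DataFrame:
    """Long-format AUC table (cell_line, drug, auc, span)."""
    records = [compute_auc(c, normalized=normalized) for c in curves]
    return pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in records],
            "drug": [r.drug for r in records],
            "auc": [r.auc for r in records],
            "span": [r.span for r in records],
        }
    )
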