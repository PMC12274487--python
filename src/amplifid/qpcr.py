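"""qPCR standard curves, amplification efficiency and LOD comparisons.

A dilution series yields one average Cq per template concentration; Cq is
linear in log10(concentration) for a well-behaved reaction, and the slope m
of the least-squares line gives the per-cycle amplification efficiency

    E = 10^(-1/m) - 1

(E = 1, i.e. 100%, for the perfect-doubling slope m = -1/log10(2) ≈ -3.32).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


def pcr_efficiency(m: float) -> float:
    """Per-cycle efficiency E = 10^(-1/m) - 1 from the standard-curve slope.

    The slope must be negative: Cq decreases as template increases.
    """
    if m >= 0:
        raise ValueError("standard-curve slope must be negative")
    return 10.0 ** (-1.0 / m) - 1.0


def lod_fold_change(lod_ref: float, lod_test: float) -> float:
    """Sensitivity gain of a test enzyme: LOD(reference) / LOD(test).

    LODs are lowest reliably detected template amounts (copies); a ratio of
    100 means the test enzyme detects 100-fold less template.
    """
    if lod_ref <= 0 or lod_test <= 0:
        raise ValueError("LODs must be positive copy numbers")
    return lod_ref / lod_test


@dataclass
class StandardCurve:
    """Fitted standard curve: Cq = m * log10(concentration) + b."""

    log10_concentration: np.ndarray  # replicate-averaged x
    cq: np.ndarray  # replicate-averaged y
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float

    @property
    def efficiency(self) -> float:
        return pcr_efficiency(self.slope)

    @property
    def efficiency_percent(self) -> float:
        return 100.0 * self.efficiency

    def predict(self, concentration) -> np.ndarray:
        return self.slope * np.log10(np.asarray(concentration, float)) + self.intercept

    def summary(self) -> str:
        lines = [
            "Standard curve (OLS of average Cq on log10 concentration)",
            "-" * 58,
            f"points (distinct concentrations) {len(self.cq):>12d}",
            f"slope m                          {self.slope:>12.4f}  (SE {self.slope_stderr:.4f})",
            f"intercept b                      {self.intercept:>12.4f}",
            f"R-squared                        {self.r_squared:>12.4f}",
            f"efficiency E = 10^(-1/m) - 1     {self.efficiency:>12.4f}  ({self.efficiency_percent:.1f}%)",
        ]
        return "\n".join(lines)


def fit_standard_curve(
    points: Sequence[tuple[float, float]] | pd.DataFrame,
) -> StandardCurve:
    """Least-squares standard curve from (concentration, Cq) observations.

    ``points`` is either an iterable of (concentration, Cq) tuples or a
    DataFrame with columns ``concentration`` and ``cq``.  Replicate Cq
    values at the same concentration are averaged before the regression.
    """
    if isinstance(points, pd.DataFrame):
        df = points.rename(columns=str.lower)[["concentration", "cq"]].copy()
    else:
        df = pd.DataFrame(points, columns=["concentration", "cq"])
    if (df["concentration"] <= 0).any():
        raise ValueError("concentrations must be positive")
    averaged = (
        df.groupby("concentration", sort=True)["cq"].mean().reset_index()
    )
    if len(averaged) < 2:
        raise ValueError("need at least two distinct concentrations")
    x = np.log10(averaged["concentration"].to_numpy(float))
    y = averaged["cq"].to_numpy(float)
    fit = stats.linregress(x, y)
    return StandardCurve(
        log10_concentration=x,
        cq=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_stderr=float(fit.stderr) if np.isfinite(fit.stderr) else 0.0,
    )


class StandardCurveModel:
    """statsmodels-style wrapper: build from a Cq table, ``fit()`` the curve.

    The table needs ``concentration`` and ``cq`` columns (``replicate`` and
    ``target`` columns are tolerated and ignored / used for grouping by the
    caller).
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data

    @classmethod
    def from_table(cls, path: str | Path, sep: str | None = None) -> "StandardCurveModel":
        sep = sep or ("\t" if str(path).endswith((".tsv", ".tab")) else ",")
        return cls(pd.read_csv(path, sep=sep))

    def fit(self) -> StandardCurve:
        return fit_standard_curve(self.data)
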