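"""Linear amperometric calibration: steady-state current density vs glucose
concentration, and inverse concentration prediction.

Units follow the sensing literature at this layer: concentration in mM,
current density in uA cm^-2, sensitivity (slope) in uA cm^-2 mM^-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats

from .fitting import adjusted_r2

__all__ = ["CalibrationResult", "fit_calibration", "predict_concentration"]


@dataclass(frozen=True)
class CalibrationResult:
    """OLS line j = a + b x with per-coefficient standard errors."""

    a: float
    b: float
    stderr_a: float
    stderr_b: float
    adj_r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError(f"calibration needs >= 3 points, got {self.n_points}")
        if not np.isfinite(self.b):
            raise ValueError("slope must be finite")


def fit_calibration(points: Sequence[Tuple[float, float]]) -> CalibrationResult:
    """Ordinary least-squares calibration line through (concentration mM,
    current density uA cm^-2) points.

    Requires at least 3 points spanning more than one distinct concentration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, current_density) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(x) < 3:
        raise ValueError(f"calibration needs >= 3 points, got {len(x)}")
    if np.unique(x).size < 2 or np.var(x) == 0.0:
        raise ValueError("concentrations have zero variance; slope is undefined")

    res = stats.linregress(x, y)
    residuals = y - (res.intercept + res.slope * x)
    return CalibrationResult(
        a=float(res.intercept),
        b=float(res.slope),
        stderr_a=float(res.intercept_stderr),
        stderr_b=float(res.stderr),
        adj_r2=adjusted_r2(residuals, y, 1),
        n_points=len(x),
    )


def predict_concentration(result: CalibrationResult, j: float) -> float:
    """Invert the calibration line: x = (j - a) / b, in mM."""
    if result.b == 0:
        raise ZeroDivisionError("zero sensitivity: concentration is not identifiable")
    return (j - result.a) / result.b
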