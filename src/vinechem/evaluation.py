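"""Calibration/prediction metrics and coefficient influence bands.

R-squared, RMSE and the residual predictive deviation (RPD) follow the
standard chemometrics definitions:

    R2   = 1 - sum((y - yhat)^2) / sum((y - ybar)^2)
    RMSE = sqrt(mean((y - yhat)^2))
    RPD  = SD(y) / RMSE,   SD with the n-1 divisor

which ties the three together through the identity
RPD = sqrt(n / ((n-1) (1-R2))). RPD above 2 is read as robust predictive
performance, 1.4-2.0 as acceptable for rough screening, below 1.4 as poor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    rpd: float
    n: int

    def as_dict(self) -> dict[str, float | int]:
        return {"r2": self.r2, "rmse": self.rmse, "rpd": self.rpd, "n": self.n}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R2/RMSE/RPD of predictions against reference values.

    R2 uses the evaluated set's own mean; a perfect fit reports RPD as the
    +inf sentinel rather than erroring, so exact synthetic fits survive.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size != p.size:
        raise MetricsError("y_true and y_pred lengths differ")
    if y.size < 2:
        raise MetricsError("need at least 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise MetricsError("constant y_true: R2 and RPD undefined")
    ss_res = float(np.sum((y - p) ** 2))
    rmse = math.sqrt(ss_res / y.size)
    r2 = 1.0 - ss_res / ss_tot
    sd = math.sqrt(ss_tot / (y.size - 1))
    rpd = math.inf if rmse == 0 else sd / rmse
    return Metrics(r2=r2, rmse=rmse, rpd=rpd, n=int(y.size))


def rpd_category(rpd: float) -> str:
    """'robust' above 2, 'acceptable' in [1.4, 2.0], 'poor' below 1.4."""
    if rpd <= 0:
        raise MetricsError("RPD must be positive")
    if rpd > 2.0:
        return "robust"
    if rpd >= 1.4:
        return "acceptable"
    return "poor"


@dataclass(frozen=True)
class CoefficientBands:
    """Wavelength indices split by |coefficient| rank into influence bands."""

    high: tuple[int, ...]    # top quarter
    medium: tuple[int, ...]  # middle half
    low: tuple[int, ...]     # bottom quarter


def coefficient_bands(coefficients: np.ndarray) -> CoefficientBands:
    """Partition wavelengths into top-25% / middle-50% / bottom-25% influence.

    Ranking is by absolute coefficient, descending; ties resolve to the
    lower index, which lands tied coefficients in the more influential band.
    """
    coef = np.asarray(coefficients, dtype=float).ravel()
    n = coef.size
    if n < 4:
        raise MetricsError("need at least 4 coefficients")
    order = sorted(range(n), key=lambda i: (-abs(coef[i]), i))
    n_high = int(math.floor(0.25 * n + 0.5))
    n_low = int(math.floor(0.25 * n + 0.5))
    high = order[:n_high]
    low = order[n - n_low:]
    medium = order[n_high : n - n_low]
    return CoefficientBands(
        high=tuple(sorted(high)),
        medium=tuple(sorted(medium)),
        low=tuple(sorted(low)),
    )
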