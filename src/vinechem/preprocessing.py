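"""Spectral preprocessing operators with a fit-on-train / apply-to-both contract.

Six methods, one applied at a time: detrending (DT), first derivative (FD),
multiplicative scatter correction (MSC), Savitzky-Golay smoothing (SG),
standard normal variate (SNV), and per-wavelength standard scaling (SS).
SNV, DT, FD and SG are row-wise and learn nothing; MSC learns the training
mean spectrum and SS learns per-wavelength training statistics, so applying
a fitted preprocessor to the test set can never leak test information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np
from scipy.signal import savgol_filter


class PreprocessingError(ValueError):
    pass


class Method(str, Enum):
    NONE = "none"
    DT = "dt"
    FD = "fd"
    MSC = "msc"
    SG = "sg"
    SNV = "snv"
    SS = "ss"


#: methods that learn statistics from the training set
_LEARNING = {Method.MSC, Method.SS}


@dataclass(frozen=True)
class PreprocessorSpec:
    """Method choice plus its parameters.

    window/polyorder apply to SG and FD (window must be odd and larger than
    polyorder); detrend_order applies to DT.
    """

    method: Method = Method.NONE
    window: int = 11
    polyorder: int = 2
    detrend_order: int = 2

    def __post_init__(self) -> None:
        method = Method(self.method)
        object.__setattr__(self, "method", method)
        if method in (Method.SG, Method.FD):
            if self.window % 2 == 0 or self.window <= self.polyorder:
                raise PreprocessingError(
                    f"window must be odd and > polyorder, got "
                    f"window={self.window}, polyorder={self.polyorder}"
                )
        if method is Method.DT and self.detrend_order < 1:
            raise PreprocessingError("detrend order must be >= 1")


@dataclass(frozen=True)
class FittedPreprocessor:
    spec: PreprocessorSpec
    wavelengths: np.ndarray
    learned: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        needs = self.spec.method in _LEARNING
        if needs != bool(self.learned):
            raise PreprocessingError(
                "learned statistics present iff method is MSC or SS"
            )


def fit(
    spec: PreprocessorSpec, train_spectra: np.ndarray, wavelengths: np.ndarray
) -> FittedPreprocessor:
    """Learn any training-set statistics the method needs.

    MSC stores the column-wise mean spectrum of the training set; SS stores
    per-wavelength means and sample standard deviations (n-1). All other
    methods are purely row-wise and store nothing.
    """
    X = np.asarray(train_spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise PreprocessingError("training spectra must be a non-empty matrix")
    if X.shape[1] != wavelengths.size:
        raise PreprocessingError("spectra/wavelength length mismatch")

    learned: dict[str, Any] = {}
    if spec.method is Method.MSC:
        learned["reference"] = X.mean(axis=0)
    elif spec.method is Method.SS:
        sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise PreprocessingError(
                f"zero-variance wavelength columns for SS: {zero[:5].tolist()}"
            )
        learned["mean"] = X.mean(axis=0)
        learned["sd"] = sd
    return FittedPreprocessor(spec=spec, wavelengths=wavelengths, learned=learned)


def transform(fp: FittedPreprocessor, spectra: np.ndarray) -> np.ndarray:
    """Apply the fitted preprocessor; output has the input's shape."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[1] != fp.wavelengths.size:
        raise PreprocessingError(
            f"expected {fp.wavelengths.size} wavelength columns, got {X.shape}"
        )
    method, spec = fp.spec.method, fp.spec

    if method is Method.NONE:
        return X.copy()

    if method is Method.SNV:
        sd = X.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise PreprocessingError("SNV undefined for constant rows")
        return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    if method is Method.MSC:
        ref = fp.learned["reference"]
        # per row least squares: row ~ a + b * ref
        A = np.column_stack([np.ones_like(ref), ref])
        coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)
        a, b = coef[0], coef[1]
        if np.any(np.abs(b) < 1e-12):
            raise PreprocessingError("MSC slope below 1e-12 for some row")
        return (X - a[:, None]) / b[:, None]

    if method is Method.SG:
        return savgol_filter(
            X, window_length=spec.window, polyorder=spec.polyorder,
            deriv=0, axis=1, mode="interp",
        )

    if method is Method.FD:
        delta = float(np.median(np.diff(fp.wavelengths)))
        return savgol_filter(
            X, window_length=spec.window, polyorder=spec.polyorder,
            deriv=1, delta=delta, axis=1, mode="interp",
        )

    if method is Method.DT:
        # subtract per-row least-squares polynomial in wavelength
        t = fp.wavelengths
        t = (t - t.mean()) / (t.max() - t.min())  # conditioning
        V = np.vander(t, spec.detrend_order + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
        return X - (V @ coef).T

    if method is Method.SS:
        return (X - fp.learned["mean"]) / fp.learned["sd"]

    raise PreprocessingError(f"unhandled method {method}")  # pragma: no cover


def fit_transform(
    spec: PreprocessorSpec, train: np.ndarray, wavelengths: np.ndarray
) -> tuple[FittedPreprocessor, np.ndarray]:
    fp = fit(spec, train, wavelengths)
    return fp, transform(fp, train)
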