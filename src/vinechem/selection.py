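"""Feature-wavelength selection by the successive projections algorithm.

Candidate subsets come from classic SPA chains: starting from one column,
each step appends the wavelength whose column has the largest norm after
projection onto the orthogonal complement of the columns already chosen,
which keeps collinearity in the selected set low. Subset size is then scored
by Monte-Carlo cross-validated RMSE (RMSECV): fold assignments are
resampled ``mc_runs`` times and a small inner regression (MLR by default,
PLS1 optionally) is cross-validated on each candidate prefix; the size with
minimal mean RMSECV wins (ties to the smaller size). The RMSECV curve and
the coefficient path across sizes are retained for diagnostic plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SPAConfig:
    max_vars: int = 50
    cv_folds: int = 10
    mc_runs: int = 80
    inner_model: str = "mlr"   # "mlr" or "pls1"
    seed: int = 0
    #: when set, the final subset size is forced to min(force_size, max_vars)
    #: regardless of where the RMSECV minimum falls
    force_size: int | None = None

    def __post_init__(self) -> None:
        if self.max_vars < 1:
            raise SelectionError("max_vars must be >= 1")
        if self.cv_folds < 2:
            raise SelectionError("cv_folds must be >= 2")
        if self.mc_runs < 1:
            raise SelectionError("mc_runs must be >= 1")
        if self.inner_model not in ("mlr", "pls1"):
            raise SelectionError("inner_model must be 'mlr' or 'pls1'")


@dataclass(frozen=True)
class SelectionResult:
    selected_indices: tuple[int, ...]
    chosen_size: int
    rmsecv_curve: np.ndarray          # RMSECV per candidate size 1..max
    coefficient_paths: np.ndarray     # (max, max) coefs of each prefix fit
    start_index: int
    chain: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.chosen_size != len(self.selected_indices):
            raise SelectionError("chosen_size must equal |selected_indices|")


def spa_chain(X: np.ndarray, start_index: int, k: int) -> tuple[int, ...]:
    """Orthogonal-projection chain of ``k`` column indices from ``start_index``.

    Columns are mean-centered internally. At each step every unselected
    column is projected onto the orthogonal complement of the span of the
    selected columns and the column of maximal residual norm is appended
    (ties to the lowest index).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 0 <= start_index < p:
        raise SelectionError("start_index out of range")
    if not 1 <= k <= min(n - 1, p):
        raise SelectionError(f"k must be in [1, min(n_train-1, n_wavelengths)] = [1, {min(n - 1, p)}]")

    R = X - X.mean(axis=0)        # residuals after projecting out selections
    chain = [start_index]
    selected = np.zeros(p, dtype=bool)
    selected[start_index] = True
    for _ in range(k - 1):
        v = R[:, chain[-1]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise SelectionError("rank exhausted before reaching k variables")
        q = v / nv
        R = R - np.outer(q, q @ R)  # one modified Gram-Schmidt sweep
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        best = float(norms.max())
        if best < 1e-12:
            raise SelectionError("rank exhausted before reaching k variables")
        pick = int(np.argmax(norms))  # argmax returns the lowest tied index
        chain.append(pick)
        selected[pick] = True
    return tuple(chain)


def _fit_linear(Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """MLR coefficients (intercept first) by least squares."""
    A = np.column_stack([np.ones(len(Xs)), Xs])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef

def _cv_rmse(
    Xs: np.ndarray, y: np.ndarray, folds: np.ndarray, n_folds: int,
    inner_model: str,
) -> float:
    """RMSE pooled over held-out folds; +inf when a fold is under-determined."""
    press = 0.0
    for f in range(n_folds):
        hold = folds == f
        Xtr, ytr = Xs[~hold], y[~hold]
        if inner_model == "mlr" and Xtr.shape[0] < Xs.shape[1] + 1:
            return np.inf
        if inner_model == "pls1":
            ncomp = min(Xs.shape[1], Xtr.shape[0] - 1)
            if ncomp < 1:
                return np.inf
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(Xtr, ytr)
            pred = pls.predict(Xs[hold]).ravel()
        else:
            coef = _fit_linear(Xtr, ytr)
            pred = coef[0] + Xs[hold] @ coef[1:]
        press += float(np.sum((y[hold] - pred) ** 2))
    return float(np.sqrt(press / len(y)))


def select_wavelengths(
    Xtrain: np.ndarray, ytrain: np.ndarray, config: SPAConfig
) -> SelectionResult:
    """Run SPA candidate generation plus Monte-Carlo RMSECV size scoring."""
    X = np.asarray(Xtrain, dtype=float)
    y = np.asarray(ytrain, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise SelectionError("X and y are not aligned")
    max_vars = min(config.max_vars, n - 1, p)

    # default start: the column most correlated (absolutely) with y
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.linalg.norm(Xc, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Xc.T @ yc) / np.where(denom == 0, np.inf, denom)
    start_index = int(np.argmax(corr))

    chain = spa_chain(X, start_index, max_vars)

    rng = np.random.default_rng(config.seed)
    n_folds = min(config.cv_folds, n)
    # one set of fold assignments per Monte-Carlo run, shared across sizes
    assignments = [
        rng.permutation(np.arange(n) % n_folds) for _ in range(config.mc_runs)
    ]

    rmsecv = np.empty(max_vars)
    coef_paths = np.zeros((max_vars, max_vars))
    for m in range(1, max_vars + 1):
        cols = list(chain[:m])
        Xs = X[:, cols]
        scores = [
            _cv_rmse(Xs, y, folds, n_folds, config.inner_model)
            for folds in assignments
        ]
        rmsecv[m - 1] = float(np.mean(scores))
        if not np.isfinite(rmsecv[m - 1]):
            logger.warning("inner model singular at subset size %d", m)
        full = _fit_linear(Xs, y)
        coef_paths[m - 1, :m] = full[1:]

    if config.force_size is not None:
        chosen = min(config.force_size, max_vars)
    else:
        # smallest size whose RMSECV ties the minimum; the tiny absolute
        # slack keeps exact-fit plateaus (RMSECV ~ machine epsilon for every
        # size past the true one) from resolving to a larger subset
        best = float(np.min(rmsecv))
        tol = 1e-12 * max(1.0, abs(best))
        chosen = int(np.argmax(rmsecv <= best + tol)) + 1
    return SelectionResult(
        selected_indices=tuple(chain[:chosen]),
        chosen_size=chosen,
        rmsecv_curve=rmsecv,
        coefficient_paths=coef_paths,
        start_index=start_index,
        chain=chain,
    )
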