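"""The three regression engines behind one train/predict contract.

PLS picks its number of latent variables by 5-fold cross-validated RMSE and
exposes per-wavelength coefficients; SVR runs the fixed randomized
hyperparameter search (10 draws from C x gamma x kernel, 5-fold CV); the
CNN trains the fixed three-conv-block architecture with Adam on MSE loss,
monitoring per-epoch loss on the calibration set and, optionally, on a
held-out prediction set (monitoring only — held-out data never influence
the weights). All engines are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.svm import SVR

from .nn import Adam, SpectralCNN, feature_map_lengths

#: the randomized-search grid for SVR
SVR_GRID: dict[str, list] = {
    "C": [0.1, 1, 10, 100],
    "gamma": ["scale", "auto", 0.01, 0.1, 1],
    "kernel": ["linear", "rbf", "sigmoid"],
}
SVR_N_ITER = 10


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str               # "pls" | "svr" | "cnn"
    hyper: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("pls", "svr", "cnn"):
            raise ModelError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float]
    eval_loss: list[float] | None = None


@dataclass
class TrainedModel:
    algorithm: str
    predictor: Callable[[np.ndarray], np.ndarray]
    diagnostics: dict[str, Any]
    n_vars: int
    history: TrainingHistory | None = None


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """One finite prediction per row; CNN runs with dropout disabled."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_vars:
        raise ModelError(
            f"model expects {model.n_vars} wavelengths, got {X.shape[1]}"
        )
    out = np.asarray(model.predictor(X), dtype=float).ravel()
    return out


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ModelError("X and y are not aligned")
    if X.shape[1] == 0:
        raise ModelError("no wavelength variables")
    if np.var(y) == 0:
        raise ModelError("constant response: nothing to regress")
    return X, y


# ---------------------------------------------------------------------------
# PLS


def train_pls(
    X: np.ndarray,
    y: np.ndarray,
    cv_folds: int = 5,
    max_components: int | None = 20,
    forced_components: int | None = None,
) -> TrainedModel:
    """PLS1 with the latent-variable count chosen by 5-fold CV RMSE.

    The candidate grid runs from 1 to min(n_train, n_vars), optionally
    capped by ``max_components`` (default 20, ample for spectra);
    ``forced_components`` skips the search. The final model is refit on all
    training rows and its coefficients are exposed on the wavelength scale.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < cv_folds:
        raise ModelError("fewer training rows than CV folds")
    limit = min(n, p)
    if max_components is not None:
        limit = min(limit, max_components)

    if forced_components is not None:
        best_ncomp = forced_components
    else:
        cv = KFold(n_splits=cv_folds, shuffle=False)
        scores = np.full(limit, np.inf)
        folds = list(cv.split(X))
        for ncomp in range(1, limit + 1):
            press, ok = 0.0, True
            for tr, te in folds:
                if ncomp > min(len(tr), p):
                    ok = False
                    break
                pls = PLSRegression(n_components=ncomp, scale=False)
                pls.fit(X[tr], y[tr])
                press += float(np.sum((y[te] - pls.predict(X[te]).ravel()) ** 2))
            if ok:
                scores[ncomp - 1] = np.sqrt(press / n)
        best_ncomp = int(np.argmin(scores)) + 1

    final = PLSRegression(n_components=best_ncomp, scale=False)
    final.fit(X, y)
    coef = np.asarray(final.coef_).reshape(-1)

    return TrainedModel(
        algorithm="pls",
        predictor=lambda Z: final.predict(Z).ravel(),
        diagnostics={"n_components": best_ncomp, "coefficients": coef},
        n_vars=p,
    )


# ---------------------------------------------------------------------------
# SVR


def train_svr(X: np.ndarray, y: np.ndarray, seed: int = 0) -> TrainedModel:
    """Randomized search (10 draws, 5-fold CV RMSE) over the fixed SVR grid."""
    X, y = _check_xy(X, y)
    if X.shape[0] < 5:
        raise ModelError("SVR search needs at least 5 training rows")
    search = RandomizedSearchCV(
        SVR(),
        SVR_GRID,
        n_iter=SVR_N_ITER,
        cv=5,
        scoring="neg_root_mean_squared_error",
        random_state=seed,
    )
    search.fit(X, y)
    best = search.best_estimator_
    return TrainedModel(
        algorithm="svr",
        predictor=lambda Z: best.predict(Z),
        diagnostics={"best_params": dict(search.best_params_)},
        n_vars=X.shape[1],
    )


# ---------------------------------------------------------------------------
# CNN


def train_cnn(
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 500,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 16,
    dropout: float = 0.2,
    X_eval: np.ndarray | None = None,
    y_eval: np.ndarray | None = None,
) -> TrainedModel:
    """Train the fixed 1-D CNN; inputs and targets are standardized internally.

    Per-wavelength input z-scores and the target z-score are fitted on the
    training set only and inverted at prediction time. Loss history is
    recorded each epoch in original target units, on the calibration set
    and, when given, on the held-out set (monitoring only).
    """
    X, y = _check_xy(X, y)
    if epochs < 1:
        raise ModelError("epochs must be >= 1")
    n, p = X.shape
    feature_map_lengths(p)  # validates the input length

    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0, ddof=0)
    x_sd[x_sd == 0] = 1.0
    y_mean, y_sd = float(y.mean()), float(y.std(ddof=0))
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    net = SpectralCNN(input_length=p, seed=seed, dropout=dropout)
    opt = Adam(net.parameters, lr=lr)
    rng = np.random.default_rng(seed + 1)

    def eval_mse(Xq: np.ndarray, yq: np.ndarray) -> float:
        pred = net.forward((Xq - x_mean) / x_sd, training=False) * y_sd + y_mean
        return float(np.mean((yq - pred) ** 2))

    train_hist: list[float] = []
    eval_hist: list[float] | None = [] if X_eval is not None else None
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = net.forward(Xs[idx], training=True)
            grad = 2.0 * (pred - ys[idx]) / idx.size
            net.backward(grad)
            opt.step(net.gradients)
        train_hist.append(eval_mse(X, y))
        if eval_hist is not None:
            eval_hist.append(eval_mse(np.asarray(X_eval, float),
                                      np.asarray(y_eval, float).ravel()))

    history = TrainingHistory(train_loss=train_hist, eval_loss=eval_hist)

    def predictor(Z: np.ndarray) -> np.ndarray:
        return net.forward((Z - x_mean) / x_sd, training=False) * y_sd + y_mean

    return TrainedModel(
        algorithm="cnn",
        predictor=predictor,
        diagnostics={
            "epochs": epochs, "lr": lr, "batch_size": batch_size,
            "feature_map_lengths": feature_map_lengths(p),
        },
        n_vars=p,
        history=history,
    )


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    X_eval: np.ndarray | None = None,
    y_eval: np.ndarray | None = None,
) -> TrainedModel:
    """Dispatch to the engine named by ``spec.algorithm``."""
    if spec.algorithm == "pls":
        return train_pls(X, y, **spec.hyper)
    if spec.algorithm == "svr":
        return train_svr(X, y, seed=spec.seed, **spec.hyper)
    return train_cnn(
        X, y, seed=spec.seed, X_eval=X_eval, y_eval=y_eval, **spec.hyper
    )
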