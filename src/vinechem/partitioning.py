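"""SPXY sample-set partitioning on joint spectral/response distances.

The SPXY scheme extends Kennard-Stone accretion to a joint distance
d(i,j) = d_x(i,j)/max d_x + d_y(i,j)/max d_y, so the calibration set spans
both the spectral space and the response distribution. The two samples at
maximal joint distance seed the training set; samples are then added one at
a time by the max-min rule until the requested training size is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform


class PartitionError(ValueError):
    pass


@dataclass(frozen=True)
class SplitResult:
    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    train_fraction: float
    indicator: str = ""

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise PartitionError("train and test indices overlap")
        n = len(train) + len(test)
        if train | test != set(range(n)):
            raise PartitionError("train/test must partition 0..N-1")
        if len(train) < 2:
            raise PartitionError("training set needs at least 2 samples")


def spxy_split(
    X: np.ndarray,
    y: np.ndarray,
    train_fraction: float = 0.7,
    indicator: str = "",
) -> SplitResult:
    """Partition samples by the SPXY joint-distance max-min rule.

    ``round(train_fraction * N)`` samples (half-up rounding) go to training;
    ties in any argmax break to the lowest index, making the split fully
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise PartitionError("need at least 3 samples")
    if y.shape[0] != n:
        raise PartitionError("X and y row counts differ")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise PartitionError("X and y must be finite")
    if not 0.0 < train_fraction <= 1.0:
        raise PartitionError("train_fraction must be in (0, 1]")
    n_train = int(np.floor(train_fraction * n + 0.5))
    if n_train < 2:
        raise PartitionError("train_fraction selects fewer than 2 samples")

    dx = squareform(pdist(X, metric="euclidean"))
    dy = squareform(pdist(y[:, None], metric="euclidean"))
    if dx.max() == 0 or dy.max() == 0:
        raise PartitionError("degenerate data: all-equal X or y")
    d = dx / dx.max() + dy / dy.max()

    # seed pair: maximal joint distance, lowest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    k = int(np.argmax(flat))
    selected = [int(iu[0][k]), int(iu[1][k])]
    selected.sort()

    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    # min distance from each remaining sample to the selected set
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_train:
        candidates = np.flatnonzero(remaining)
        pick = int(candidates[np.argmax(min_d[candidates])])
        selected.append(pick)
        remaining[pick] = False
        min_d = np.minimum(min_d, d[pick])

    test = [i for i in range(n) if remaining[i]]
    return SplitResult(
        train_indices=tuple(sorted(selected)),
        test_indices=tuple(test),
        train_fraction=train_fraction,
        indicator=indicator,
    )
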