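"""SPA projection chains and Monte-Carlo RMSECV subset-size scoring."""

import numpy as np
import pytest

from vinechem import SPAConfig, select_wavelengths, spa_chain
from vinechem.selection import SelectionError


def projection_oracle_chain(X, start, k):
    """Exhaustive orthogonal-projection replay: at each step compute every
    unselected column's residual after projecting onto the span of the
    selected (centered) columns via the explicit projector P = A A^+."""
    Xc = X - X.mean(axis=0)
    chain = [start]
    for _ in range(k - 1):
        A = Xc[:, chain]
        P = A @ np.linalg.pinv(A)
        best_norm, best_j = -1.0, None
        for j in range(X.shape[1]):
            if j in chain:
                continue
            r = Xc[:, j] - P @ Xc[:, j]
            norm = np.linalg.norm(r)
            if norm > best_norm + 1e-12:
                best_norm, best_j = norm, j
        chain.append(best_j)
    return chain


def _residual(Xc, chain, j):
    A = Xc[:, chain]
    return Xc[:, j] - A @ np.linalg.pinv(A) @ Xc[:, j]


class TestChain:
    def test_orthogonal_columns_picked_by_norm(self):
        # orthogonal columns with norms 3, 2, 1; start at the norm-2 column
        X = np.diag([3.0, 2.0, 1.0])
        X = np.vstack([X, np.zeros(3)])  # n > k
        assert spa_chain(X, start_index=1, k=2) == (1, 0)

    def test_collinear_column_avoided(self):
        rng = np.random.default_rng(0)
        c1, c2 = rng.random(8), rng.random(8)
        X = np.column_stack([c1, c2, c1 + c2])
        chain = spa_chain(X, start_index=0, k=2)
        assert list(chain) == projection_oracle_chain(X, 0, 2)

    def test_k_one_returns_start(self, rng):
        X = rng.random((6, 4))
        assert spa_chain(X, start_index=2, k=1) == (2,)

    def test_rank_exhaustion_raises(self):
        X = np.column_stack([np.arange(5.0), 2 * np.arange(5.0), 3 * np.arange(5.0)])
        with pytest.raises(SelectionError, match="rank"):
            spa_chain(X, start_index=0, k=3)

    @pytest.mark.parametrize("seed", range(15))
    def test_random_fixtures_match_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((10, 6))
        start = int(rng.integers(0, 6))
        k = int(rng.integers(2, 6))
        assert list(spa_chain(X, start, k)) == projection_oracle_chain(X, start, k)

    def test_residual_norms_non_increasing_and_orthogonal(self, rng):
        X = rng.random((20, 12))
        chain = spa_chain(X, start_index=0, k=8)
        Xc = X - X.mean(axis=0)
        residuals = [Xc[:, chain[0]]]
        norms = [np.linalg.norm(Xc[:, chain[0]])]
        for t in range(1, len(chain)):
            r = _residual(Xc, list(chain[:t]), chain[t])
            residuals.append(r)
            norms.append(np.linalg.norm(r))
        for a in range(len(residuals)):
            for b in range(a + 1, len(residuals)):
                assert abs(residuals[a] @ residuals[b]) < 1e-8
        # the max-residual pick can only shrink as the span grows
        picked_max = [
            max(
                np.linalg.norm(_residual(Xc, list(chain[:t]), j))
                for j in range(X.shape[1]) if j not in chain[:t]
            )
            for t in range(1, len(chain))
        ]
        assert all(picked_max[i] >= picked_max[i + 1] - 1e-10
                   for i in range(len(picked_max) - 1))


class TestSelection:
    def test_planted_linear_signal_reaches_zero_rmsecv_at_three(self, rng):
        """y depends exactly on 3 columns; cross-validated error of the MLR
        inner model hits (numerical) zero at subset size 3."""
        X = 0.1 * rng.random((30, 10))
        X[:, [1, 4, 7]] = 10.0 * rng.random((30, 3))  # planted high-variance columns
        y = 2.0 * X[:, 1] - 1.5 * X[:, 4] + 0.5 * X[:, 7]
        res = select_wavelengths(X, y, SPAConfig(max_vars=10, cv_folds=5, mc_runs=3, seed=0))
        assert res.chosen_size == 3
        assert res.rmsecv_curve[2] < 1e-8
        assert set(res.selected_indices) == {1, 4, 7}

    def test_seeded_determinism(self, rng):
        X = rng.random((25, 12))
        y = rng.random(25)
        cfg = SPAConfig(max_vars=6, cv_folds=5, mc_runs=1, seed=9)
        a = select_wavelengths(X, y, cfg)
        b = select_wavelengths(X, y, cfg)
        assert a.selected_indices == b.selected_indices
        np.testing.assert_array_equal(a.rmsecv_curve, b.rmsecv_curve)

    def test_selected_count_bounded_by_max_vars(self, small_dataset):
        X = small_dataset.spectra.reflectance
        y = small_dataset.references.indicator("TSS")
        res = select_wavelengths(X, y, SPAConfig(max_vars=12, cv_folds=4, mc_runs=2, seed=1))
        assert len(res.selected_indices) == res.chosen_size <= 12
        assert all(0 <= i < X.shape[1] for i in res.selected_indices)

    def test_force_size_pins_subset_size(self, rng):
        X = rng.random((30, 20))
        y = rng.random(30)
        res = select_wavelengths(
            X, y, SPAConfig(max_vars=10, cv_folds=5, mc_runs=2, seed=0, force_size=10)
        )
        assert res.chosen_size == 10

    def test_planted_band_recovery_on_generated_spectra(self):
        """With distinct informative bands and high SNR, most selected
        wavelengths should fall within one band-width of a true center."""
        from conftest import small_config
        from vinechem import generate_dataset, ArtifactSpec

        hits, total = 0, 0
        for seed in range(20):
            cfg = small_config(seed=seed, n_samples=60,
                               artifacts=ArtifactSpec(0.0, 0.0, (), 0.0005))
            ds = generate_dataset(cfg)
            X = ds.spectra.reflectance
            y = ds.references.indicator("TSS")
            wl = ds.spectra.grid.values
            res = select_wavelengths(X, y, SPAConfig(max_vars=4, cv_folds=5, mc_runs=3, seed=seed))
            centers_widths = [(c, w) for spec in cfg.constituents for c, w, _ in spec.bands]
            for i in res.selected_indices:
                total += 1
                if any(abs(wl[i] - c) <= w for c, w in centers_widths):
                    hits += 1
        assert hits / total >= 0.8
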