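"""The six preprocessing operators: exact identities and leakage safety."""

import numpy as np
import pytest

from vinechem import ArtifactSpec, Method, PreprocessorSpec, fit, transform, generate_dataset
from vinechem.preprocessing import PreprocessingError, fit_transform

from conftest import small_config

WL = np.linspace(400.0, 700.0, 31)


def _fit(method, X, wl=WL, **kw):
    return fit(PreprocessorSpec(method=method, **kw), X, wl)


class TestSNV:
    def test_worked_row(self):
        fp = _fit(Method.SNV, np.ones((1, 3)) + 1, wl=np.array([1.0, 2.0, 3.0]))
        out = transform(fp, np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])

    def test_rows_mean_zero_sd_one_and_idempotent(self, rng):
        X = rng.random((12, 31))
        fp = _fit(Method.SNV, X)
        out = transform(fp, X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(transform(fp, out), out, atol=1e-10)

    def test_constant_row_rejected(self):
        fp = _fit(Method.SNV, np.ones((2, 31)) + np.arange(31))
        with pytest.raises(PreprocessingError, match="constant"):
            transform(fp, np.ones((1, 31)))

    def test_removes_planted_scatter_exactly(self, rng):
        """Spectra differing only by (multiplier, offset) map to the same SNV
        output — checked on generator spectra with scatter on, noise off."""
        cfg = small_config(seed=5, artifacts=ArtifactSpec(0.2, 0.05, (), 0.0))
        ds = generate_dataset(cfg)
        clean = ds.truth.clean
        observed = ds.spectra.reflectance
        wl = ds.spectra.grid.values
        fp = _fit(Method.SNV, observed, wl=wl)
        np.testing.assert_allclose(
            transform(fp, observed), transform(fp, clean), atol=1e-9
        )

    def test_independent_of_training_set(self, rng):
        X = rng.random((5, 31))
        a = transform(_fit(Method.SNV, rng.random((3, 31))), X)
        b = transform(_fit(Method.SNV, rng.random((9, 31))), X)
        np.testing.assert_array_equal(a, b)


class TestMSC:
    def test_reference_is_train_mean(self, rng):
        r = rng.random(31)
        fp = _fit(Method.MSC, np.vstack([r, 3 * r]))
        np.testing.assert_allclose(fp.learned["reference"], 2 * r)

    def test_affine_recovery(self, rng):
        r = rng.random(31) + 0.5
        fp = _fit(Method.MSC, r[None, :])
        np.testing.assert_allclose(transform(fp, r[None, :]), r[None, :], atol=1e-10)
        np.testing.assert_allclose(
            transform(fp, (2 * r + 3)[None, :]), r[None, :], atol=1e-10
        )

    def test_tiny_slope_rejected(self, rng):
        r = np.linspace(1, 2, 31)
        fp = _fit(Method.MSC, r[None, :])
        with pytest.raises(PreprocessingError, match="slope"):
            transform(fp, np.full((1, 31), 5.0))  # constant row: b = 0


class TestRowwisePolynomialMethods:
    def test_dt_order2_annihilates_quadratics(self):
        row = 0.3 + 0.002 * WL - 1e-5 * WL**2
        fp = _fit(Method.DT, row[None, :], detrend_order=2)
        np.testing.assert_allclose(transform(fp, row[None, :]), 0.0, atol=1e-10)

    def test_fd_of_linear_ramp_is_constant_slope(self):
        wl = np.arange(31, dtype=float)  # unit step
        row = 5.0 + 0.25 * wl
        fp = fit(PreprocessorSpec(method=Method.FD, window=5, polyorder=2), row[None, :], wl)
        out = transform(fp, row[None, :])
        np.testing.assert_allclose(out[0], 0.25, atol=1e-10)

    def test_fd_units_are_per_nm(self):
        wl = np.linspace(0.0, 60.0, 31)  # 2 nm step
        row = 1.0 + 0.5 * wl
        fp = fit(PreprocessorSpec(method=Method.FD, window=5, polyorder=2), row[None, :], wl)
        np.testing.assert_allclose(transform(fp, row[None, :])[0], 0.5, atol=1e-10)

    def test_sg_reproduces_polynomials_and_matches_local_fits(self, rng):
        """SG (w=5, p=2) applied to an exact quadratic returns it unchanged,
        and on arbitrary data the interior values equal direct local
        least-squares polynomial fits (the independent oracle)."""
        w, p = 5, 2
        quad = 1.0 + 0.1 * WL - 2e-4 * WL**2
        fp = fit(PreprocessorSpec(method=Method.SG, window=w, polyorder=p), quad[None, :], WL)
        np.testing.assert_allclose(transform(fp, quad[None, :])[0], quad, atol=1e-9)

        noisy = rng.random(31)
        out = transform(fp, noisy[None, :])[0]
        half = w // 2
        for i in range(half, 31 - half):
            window = noisy[i - half : i + half + 1]
            t = np.arange(-half, half + 1, dtype=float)
            coeffs = np.polynomial.polynomial.polyfit(t, window, p)
            assert out[i] == pytest.approx(coeffs[0], abs=1e-9)


class TestSS:
    def test_train_columns_standardized(self, rng):
        X = rng.random((10, 31)) * 5
        fp, out = fit_transform(PreprocessorSpec(method=Method.SS), X, WL)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_worked_column_stats(self):
        X = np.array([[1.0], [3.0]])
        fp = fit(PreprocessorSpec(method=Method.SS), X, np.array([500.0, 501.0])[:1])
        assert fp.learned["mean"][0] == 2.0
        assert fp.learned["sd"][0] == pytest.approx(np.sqrt(2))

    def test_zero_variance_column_named_in_error(self, rng):
        X = rng.random((6, 31))
        X[:, 7] = 1.0
        with pytest.raises(PreprocessingError, match="7"):
            fit(PreprocessorSpec(method=Method.SS), X, WL)


class TestContracts:
    @pytest.mark.parametrize("method", list(Method))
    def test_shape_preserved_and_deterministic(self, method, rng):
        X = rng.random((8, 31)) + 0.5
        fp = _fit(method, X)
        out1, out2 = transform(fp, X), transform(fp, X)
        assert out1.shape == X.shape
        np.testing.assert_array_equal(out1, out2)

    @pytest.mark.parametrize("method", list(Method))
    def test_test_set_transform_free_of_test_leakage(self, method, rng):
        """Transforming held-out rows uses train statistics only: the output
        for a row is unchanged when other test rows are permuted or dropped."""
        train, test = rng.random((10, 31)) + 0.5, rng.random((6, 31)) + 0.5
        fp = _fit(method, train)
        full = transform(fp, test)
        # batched LAPACK solves can differ from single-row ones in the last
        # ulp, so equality is asserted to 1e-12, far below any leakage signal
        np.testing.assert_allclose(full[2], transform(fp, test[[2]])[0], atol=1e-12)
        perm = rng.permutation(6)
        np.testing.assert_allclose(transform(fp, test[perm]), full[perm], atol=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(PreprocessingError):
            PreprocessorSpec(method=Method.SG, window=4, polyorder=2)
        with pytest.raises(PreprocessingError):
            PreprocessorSpec(method=Method.SG, window=3, polyorder=3)
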