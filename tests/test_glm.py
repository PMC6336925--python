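"""Design construction, OLS estimation, and the three serial-correlation
treatments."""

import numpy as np
import pytest

from fnirsfilt import (
    ChannelSeries,
    HemodynamicGLM,
    HRFSpec,
    build_design,
    downsample_spline,
    fit_ols,
    make_task_component,
    precolor,
    sample_hrf,
)

FS = 5.0


@pytest.fixture(scope="module")
def design(protocol, hrf):
    return build_design(protocol, hrf, FS)


class TestDesign:
    def test_task_column_unit_peak(self, design):
        assert design.task.max() == pytest.approx(1.0, abs=0)
        assert np.all(design.X[:, 1] == 1.0)

    def test_task_column_shares_generator_path(self, design, boxcar, hrf_kernel):
        comp = make_task_component(boxcar, hrf_kernel, 1.0)
        np.testing.assert_array_equal(design.task, comp.values)

    def test_task_column_not_constant(self, design):
        centered = design.task - design.task.mean()
        assert np.linalg.norm(centered) > 0

    def test_sample_count_mismatch_rejected(self, protocol, hrf):
        with pytest.raises(ValueError):
            build_design(protocol, hrf, FS, n_samples=1234)


class TestOLS:
    def test_pure_task_recovers_amplitude(self, design):
        fit = fit_ols(8e-7 * design.task, design)
        assert fit.beta_task == pytest.approx(8e-7, rel=1e-12)
        assert fit.beta_const == pytest.approx(0.0, abs=1e-18)
        assert fit.dof == design.n_samples - 2

    def test_constant_input(self, design):
        fit = fit_ols(np.full(design.n_samples, 3e-6), design)
        assert fit.beta_task == pytest.approx(0.0, abs=1e-16)
        assert fit.beta_const == pytest.approx(3e-6, rel=1e-12)

    def test_matches_normal_equations_oracle(self, design, rng):
        y = rng.normal(0, 1e-6, design.n_samples)
        fit = fit_ols(y, design)
        X = design.X
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        assert fit.beta_task == pytest.approx(beta[0], rel=1e-10)
        assert fit.beta_const == pytest.approx(beta[1], rel=1e-10)

    def test_scale_equivariance(self, design, rng):
        y = rng.normal(0, 1e-6, design.n_samples)
        f1 = fit_ols(y, design)
        f2 = fit_ols(7.0 * y, design)
        assert f2.beta_task == pytest.approx(7.0 * f1.beta_task, rel=1e-10)
        assert f2.beta_const == pytest.approx(7.0 * f1.beta_const, rel=1e-10)

    def test_nonfinite_rejected(self, design):
        y = np.zeros(design.n_samples)
        y[5] = np.nan
        with pytest.raises(ValueError):
            fit_ols(y, design)


class TestCorrections:
    @pytest.mark.parametrize("correction", ["none", "downsample", "precolor"])
    @pytest.mark.parametrize("amplitude", [8e-7, -2.7e-7])
    def test_noise_free_exact_recovery(self, boxcar, hrf_kernel, correction, amplitude):
        comp = make_task_component(boxcar, hrf_kernel, amplitude)
        est = HemodynamicGLM(correction=correction).fit(comp.values)
        assert est.beta_task_ == pytest.approx(amplitude, rel=1e-10)

    @pytest.mark.parametrize("correction", ["none", "downsample", "precolor"])
    def test_residuals_orthogonal_to_design(self, design, rng, correction):
        y = rng.normal(0, 1e-6, design.n_samples)
        est = HemodynamicGLM(correction=correction).fit(y)
        r = est.residuals_
        X = est.design_.X if correction == "none" else None
        if X is None:
            # rebuild the transformed design the estimator used
            from fnirsfilt.glm import _downsample_pair, precolor as _pc

            if correction == "precolor":
                _, D = _pc(y, est.design_, sample_hrf(HRFSpec(), FS))
            else:
                _, D = _downsample_pair(y, est.design_, FS)
            X = D.X
        for j in range(2):
            denom = np.linalg.norm(r) * np.linalg.norm(X[:, j])
            assert abs(np.dot(r, X[:, j])) / denom < 1e-8

    def test_precolor_preserves_constant_column(self, design, hrf_kernel, rng):
        y = rng.normal(0, 1e-6, design.n_samples)
        _, D = precolor(y, design, hrf_kernel)
        np.testing.assert_allclose(D.X[:, 1], 1.0, rtol=1e-12)

    def test_precolor_imposes_kernel_dominated_autocorrelation(self, design, hrf_kernel):
        """Precoloring replaces the data's intrinsic serial correlation with
        the known kernel-imposed one: precolored residual lag-1
        autocorrelation is near 1 and insensitive to the intrinsic AR
        coefficient, while the uncorrected one tracks it."""

        def lag1(r):
            r = r - r.mean()
            return float(np.dot(r[:-1], r[1:]) / np.dot(r, r))

        results = {}
        for phi in (0.2, 0.8):
            vals_n, vals_p = [], []
            for seed in range(20):
                g = np.random.default_rng(seed)
                w = g.standard_normal(design.n_samples)
                e = np.zeros_like(w)
                for i in range(1, e.size):
                    e[i] = phi * e[i - 1] + w[i]
                y = 8e-7 * design.task + 1e-7 * e / e.std()
                vals_n.append(lag1(fit_ols(y, design).residuals))
                ys, D = precolor(y, design, hrf_kernel)
                vals_p.append(lag1(fit_ols(ys, D).residuals))
            results[phi] = (np.mean(vals_n), np.mean(vals_p))
        # uncorrected lag-1 follows the AR coefficient
        assert results[0.8][0] - results[0.2][0] > 0.3
        # precolored lag-1 is kernel-dominated: high and nearly phi-independent
        assert results[0.2][1] > 0.95 and results[0.8][1] > 0.95
        assert abs(results[0.8][1] - results[0.2][1]) < 0.05


class TestDownsampling:
    def test_constant_preserved(self):
        s = ChannelSeries(np.full(2900, 4.2), FS, "HbO2")
        out = downsample_spline(s)
        assert out.fs == 1.0
        np.testing.assert_allclose(out.values, 4.2, rtol=1e-12)

    def test_linear_ramp_exact(self):
        s = ChannelSeries(np.arange(2900) / FS, FS, "HbO2")
        out = downsample_spline(s)
        np.testing.assert_allclose(out.values, np.arange(len(out)), rtol=1e-10)

    def test_sinusoid_interpolation_error_small(self):
        t = np.arange(2900) / FS
        s = ChannelSeries(np.sin(2 * np.pi * 0.05 * t), FS, "HbO2")
        out = downsample_spline(s)
        expected = np.sin(2 * np.pi * 0.05 * out.time)
        assert np.max(np.abs(out.values - expected)) < 1e-3

    def test_upsampling_rejected(self):
        s = ChannelSeries(np.zeros(100), 1.0, "HbO2")
        with pytest.raises(ValueError):
            downsample_spline(s, fs_new=2.0)


def test_hemodynamic_glm_sklearn_contract(design, rng):
    from sklearn.base import clone

    est = HemodynamicGLM(correction="precolor")
    est2 = clone(est)
    assert est2.get_params()["correction"] == "precolor"
    X = rng.normal(0, 1e-6, (design.n_samples, 3))
    est.fit(X)
    assert est.beta_task_.shape == (3,)
    assert est.predict().shape == (design.n_samples, 3)
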