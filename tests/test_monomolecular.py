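"""Monomolecular curve: prediction, Jacobian, and least-squares recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulletgrowth.monomolecular import (
    MonomolecularParams,
    MonomolecularRegressor,
    UnderDeterminedError,
    fit,
    jacobian,
    predict,
    residuals,
)
from pulletgrowth.profiles import observations_to_arrays
from pulletgrowth.synthetic import SyntheticSpec, generate_scaled

positive = st.floats(min_value=1e-3, max_value=10.0)


class TestPredict:
    def test_zero_intake_gives_minus_b(self, hyline_params):
        assert predict(hyline_params, 0.0) == pytest.approx(-0.0219)

    def test_asymptote_is_a(self, hyline_params):
        assert predict(hyline_params, 1e6) == pytest.approx(0.0861)

    def test_point_evaluation(self, isa_params):
        # frozen from direct evaluation of the exponential
        assert predict(isa_params, 0.2) == pytest.approx(-0.023404, abs=1e-6)

    def test_negative_intake_rejected(self, hyline_params):
        with pytest.raises(ValueError, match="negative"):
            predict(hyline_params, -0.1)

    @given(a=positive, b=positive, c=positive)
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_and_concave(self, a, b, c):
        params = MonomolecularParams(a=a, b=b, c=c)
        x = np.linspace(0.0, 2.0, 50)
        y = predict(params, x)
        assert np.all(np.diff(y) > 0)
        assert np.all(np.diff(y, 2) < 0)


class TestJacobian:
    @given(a=positive, b=positive, c=positive, x=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_matches_central_finite_differences(self, a, b, c, x):
        params = np.array([a, b, c])
        J = jacobian(params, np.array([x]))[0]
        for i in range(3):
            h = 1e-6 * max(params[i], 1.0)
            up, dn = params.copy(), params.copy()
            up[i] += h
            dn[i] -= h
            num = (predict(up, x) - predict(dn, x)) / (2 * h)
            assert J[i] == pytest.approx(num, abs=1e-6)


class TestFit:
    def test_noiseless_recovery_to_1e6_relative(self, noiseless_xy):
        x, y = noiseless_xy
        reg = MonomolecularRegressor().fit(x, y)
        for got, true in zip((reg.a_, reg.b_, reg.c_), (0.10, 0.15, 3.5)):
            assert abs(got - true) / true < 1e-6

    def test_init_invariance_at_global_optimum(self, noiseless_xy):
        x, y = noiseless_xy
        r1 = MonomolecularRegressor(init=(0.2, 0.2, 2.0)).fit(x, y)
        r2 = MonomolecularRegressor(init=(0.05, 0.05, 6.0)).fit(x, y)
        assert r1.a_ == pytest.approx(r2.a_, abs=1e-8)
        assert r1.b_ == pytest.approx(r2.b_, abs=1e-8)
        assert r1.c_ == pytest.approx(r2.c_, abs=1e-8)

    def test_under_determined_raises(self):
        with pytest.raises(UnderDeterminedError):
            MonomolecularRegressor().fit([0.1, 0.2, 0.3], [0.01, 0.02, 0.03])

    def test_too_few_distinct_intakes_raises(self):
        with pytest.raises(UnderDeterminedError):
            MonomolecularRegressor().fit(
                [0.1, 0.1, 0.2, 0.2], [0.01, 0.011, 0.02, 0.021]
            )

    def test_constant_gain_not_identifiable(self):
        with pytest.raises(np.linalg.LinAlgError):
            MonomolecularRegressor().fit([0.1, 0.2, 0.3, 0.4], [0.02] * 4)

    def test_covariance_matches_se_and_is_symmetric_psd(self, noiseless_xy):
        x, y = noiseless_xy
        rng = np.random.default_rng(7)
        params = fit_obs(x, y + rng.normal(0, 0.002, size=len(y)))
        cov = params.covariance
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-18)
        assert params.se_a == pytest.approx(np.sqrt(cov[0, 0]))
        assert params.se_c == pytest.approx(np.sqrt(cov[2, 2]))

    def test_agrees_with_curve_fit_oracle(self, noiseless_xy):
        """Independent cross-check of estimates and SEs via scipy curve_fit."""
        from scipy.optimize import curve_fit

        x, y = noiseless_xy
        rng = np.random.default_rng(11)
        yn = y + rng.normal(0, 0.002, size=len(y))
        reg = MonomolecularRegressor().fit(x, yn)
        popt, pcov = curve_fit(
            lambda x, a, b, c: a - (a + b) * np.exp(-c * x),
            x, yn, p0=(0.1, 0.1, 3.0),
        )
        assert np.allclose([reg.a_, reg.b_, reg.c_], popt, rtol=1e-6)
        assert np.allclose(np.sqrt(np.diag(pcov)),
                           [reg.se_a_, reg.se_b_, reg.se_c_], rtol=1e-4)

    def test_parameter_recovery_median_bias_under_noise(self):
        """Median |relative bias| < 5% per parameter over 200 noisy replicates."""
        true = np.array([0.10, 0.15, 3.5])
        errs = []
        for seed in range(200):
            spec = SyntheticSpec(noise_sd=0.002, seed=seed)
            x, y = observations_to_arrays(generate_scaled(spec))
            reg = MonomolecularRegressor().fit(x, y)
            errs.append(np.abs(np.array([reg.a_, reg.b_, reg.c_]) - true) / true)
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.05), med


class TestResiduals:
    def test_zero_on_curve(self, noiseless_xy):
        x, y = noiseless_xy
        obs = generate_scaled(SyntheticSpec(noise_sd=0.0, seed=1))
        true = MonomolecularParams(0.10, 0.15, 3.5)
        assert np.allclose(residuals(true, obs), 0.0, atol=1e-15)

    def test_single_offset_point(self, hyline_params):
        from pulletgrowth.profiles import ScaledObservation

        x0 = 0.2
        obs = [ScaledObservation(week=1, x=x0, y=predict(hyline_params, x0) + 0.01,
                                 bw_mean_g=100.0, days=7)]
        assert residuals(hyline_params, obs)[0] == pytest.approx(0.01)

    def test_rss_field_equals_sum_of_squares(self, noiseless_xy):
        x, y = noiseless_xy
        rng = np.random.default_rng(3)
        yn = y + rng.normal(0, 0.002, size=len(y))
        params = fit_obs(x, yn)
        obs = _as_obs(x, yn)
        assert params.rss == pytest.approx(np.sum(residuals(params, obs) ** 2))


def _as_obs(x, y):
    from pulletgrowth.profiles import ScaledObservation

    return [
        ScaledObservation(week=i + 1, x=float(xi), y=float(yi), bw_mean_g=100.0, days=7)
        for i, (xi, yi) in enumerate(zip(x, y))
    ]


def fit_obs(x, y):
    return fit(_as_obs(x, y))
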