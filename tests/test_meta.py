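"""Random-effects pooling: Cochran's Q, I², DL τ², and the forest layout."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulletgrowth.datasets import load_strain_parameters, strain_parameters_meta_input
from pulletgrowth.meta import (
    DerSimonianLaird,
    MetaInput,
    MetaStudy,
    cochran_q,
    dl_pool,
    forest_table,
    heterogeneity_label,
    i_squared,
    single_study_result,
)


class TestCochranQ:
    def test_identical_estimates_give_zero(self):
        q, df, p = cochran_q([1.5] * 6, [0.1] * 6)
        assert q == 0.0
        assert df == 5
        assert p == pytest.approx(1.0)

    def test_two_symmetric_studies(self):
        q, df, _ = cochran_q([0.0, 1.0], [1.0, 1.0])
        assert q == pytest.approx(0.5)
        assert df == 1

    def test_published_rate_parameter_column(self, c_column):
        est, se = c_column
        q, df, p = cochran_q(est, se)
        assert q == pytest.approx(21.137, abs=0.1)
        assert df == 5
        assert p < 0.01

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            cochran_q([1.0], [0.1])


class TestISquared:
    @pytest.mark.parametrize(
        "q, k, expected, tol",
        [
            (27.868, 6, 82.058, 0.01),
            (1263.308, 6, 99.604, 0.001),
            (21.137, 6, 76.344, 0.01),
        ],
    )
    def test_published_identities(self, q, k, expected, tol):
        assert i_squared(q, k) == pytest.approx(expected, abs=tol)

    def test_truncated_at_zero_when_q_below_df(self):
        assert i_squared(3.0, 6) == 0.0

    def test_zero_q(self):
        assert i_squared(0.0, 6) == 0.0

    def test_band_labels(self):
        assert heterogeneity_label(10.0) == "low"
        assert heterogeneity_label(50.0) == "moderate"
        assert heterogeneity_label(90.0) == "high"


class TestDLPool:
    def test_published_rate_parameter_row(self, c_column):
        est, se = c_column
        dl = DerSimonianLaird().fit(est, se)
        assert dl.pooled_ == pytest.approx(3.276, abs=0.02)
        assert dl.se_pooled_ == pytest.approx(0.380, abs=0.005)
        assert dl.ci_low_ == pytest.approx(2.531, abs=0.02)
        assert dl.ci_high_ == pytest.approx(4.021, abs=0.02)
        assert dl.i_squared_ == pytest.approx(76.344, abs=0.5)

    def test_identical_studies_collapse(self):
        dl = DerSimonianLaird().fit([2.0] * 5, [0.3] * 5)
        assert dl.pooled_ == pytest.approx(2.0)
        assert dl.tau_squared_ == 0.0
        assert dl.q_ == 0.0

    def test_symmetric_pair_pools_to_midpoint(self):
        dl = DerSimonianLaird().fit([0.0, 1.0], [1.0, 1.0])
        assert dl.pooled_ == pytest.approx(0.5)

    def test_random_weights_sum_to_inverse_pooled_variance(self, c_column):
        est, se = c_column
        dl = DerSimonianLaird().fit(est, se)
        assert np.sum(dl.weights_random_) == pytest.approx(dl.se_pooled_**-2)

    def test_zero_tau2_equals_fixed_effect(self):
        # nearly homogeneous studies: Q < df forces tau2 = 0
        est = np.array([1.00, 1.01, 0.99, 1.005])
        se = np.array([0.5, 0.5, 0.5, 0.5])
        dl = DerSimonianLaird().fit(est, se)
        w = 1 / se**2
        assert dl.tau_squared_ == 0.0
        assert dl.pooled_ == pytest.approx(float(np.sum(w * est) / np.sum(w)))

    @given(
        k=st.integers(2, 8),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_statsmodels_oracle(self, k, seed):
        """Dual-route check against statsmodels' DL implementation.

        statsmodels leaves the moment estimate of tau^2 untruncated, so the
        comparison is restricted to draws with non-negative tau^2; the
        truncated branch is covered by test_zero_tau2_equals_fixed_effect.
        """
        from hypothesis import assume
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(seed)
        est = rng.normal(0, 2, size=k)
        se = rng.uniform(0.05, 1.5, size=k)
        ref = combine_effects(est, se**2, method_re="dl")
        assume(float(ref.tau2) >= 0)
        dl = DerSimonianLaird().fit(est, se)
        assert dl.tau_squared_ == pytest.approx(float(ref.tau2), abs=1e-10)
        assert dl.pooled_ == pytest.approx(float(ref.mean_effect_re), abs=1e-10)
        assert dl.se_pooled_ == pytest.approx(float(ref.sd_eff_w_re), abs=1e-10)

    def test_k1_passthrough(self):
        mi = MetaInput("a", (MetaStudy("only", 1.0, 0.1),))
        res = single_study_result(mi)
        assert res.pooled == 1.0
        assert res.tau_squared == 0.0
        assert res.ci_low == pytest.approx(1.0 - 1.96 * 0.1)

    def test_recovery_of_true_mean_under_heterogeneity(self, c_column):
        """K=6 studies, mu=3, tau2=0.6: mean pooled estimate near mu."""
        from pulletgrowth.synthetic import generate_meta_studies

        _, se = c_column
        pooled = []
        for rep in range(300):
            mi = generate_meta_studies(6, 3.0, 0.6, se, seed=rep)
            pooled.append(dl_pool(mi).pooled)
        assert abs(np.mean(pooled) - 3.0) / 3.0 < 0.02


class TestForestTable:
    def test_layout_and_weights(self, c_column):
        mi = strain_parameters_meta_input("c")
        res = dl_pool(mi)
        table = forest_table(res, mi)
        assert len(table) == 7  # six strains + summary
        studies = table[table["kind"] == "study"]
        assert studies["weight_pct"].sum() == pytest.approx(100.0)
        summary = table[table["kind"] == "summary"].iloc[0]
        assert summary["ci_low"] == pytest.approx(res.ci_low)
        assert summary["ci_high"] == pytest.approx(res.ci_high)

    def test_study_ci_is_plus_minus_196_se(self):
        mi = MetaInput("a", (MetaStudy("s", 1.0, 0.1), MetaStudy("t", 1.2, 0.2)))
        table = forest_table(dl_pool(mi), mi)
        row = table.iloc[0]
        assert row["ci_low"] == pytest.approx(0.804)
        assert row["ci_high"] == pytest.approx(1.196)


def test_packaged_parameter_table_shape():
    df = load_strain_parameters()
    assert len(df) == 18
    assert set(df["parameter"]) == {"a", "b", "c"}
    assert (df["se"] > 0).all()
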