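"""Probabilistic sensitivity analysis: distributions, sampling, CEAC, CE plane."""

import numpy as np
import pandas as pd
import pytest

from gdcea.cea import run_base_case
from gdcea.gd_model import LIVE_STATES, default_parameters
from gdcea.psa import (
    PSAConfig,
    beta_from_mean_se,
    ce_plane_summary,
    ceac,
    run_psa,
    sample_beta,
    sample_parameter_set,
    sample_truncated_normal,
)


class TestBetaFromMeanSE:
    def test_symmetric_case(self):
        assert beta_from_mean_se(0.5, 0.1) == pytest.approx((12.0, 12.0))

    def test_utility_case(self):
        a, b = beta_from_mean_se(0.86, 0.086)
        assert a == pytest.approx(13.1400, abs=1e-4)
        assert b == pytest.approx(2.1391, abs=1e-4)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_from_mean_se(0.5, 0.6)
        with pytest.raises(ValueError):
            beta_from_mean_se(1.2, 0.1)

    def test_moment_recovery_at_large_n(self, rng):
        # sampled draws reproduce the requested mean and SE
        mean, se, n = 0.86, 0.086, 10_000
        a, b = beta_from_mean_se(mean, se)
        draws = rng.beta(a, b, size=n)
        mc_se = se / np.sqrt(n)
        assert abs(draws.mean() - mean) < 3 * mc_se
        # SE of the sample SD is ~ se/sqrt(2n) for near-normal shapes
        assert abs(draws.std(ddof=1) - se) < 5 * se / np.sqrt(2 * n)


class TestTruncatedNormal:
    def test_sample_mean_near_target(self, rng):
        draws = [sample_truncated_normal(rng, 21_870, 2_187) for _ in range(1000)]
        assert abs(np.mean(draws) - 21_870) < 3 * 2_187 / np.sqrt(1000)

    def test_zero_se_degenerates_to_mean(self, rng):
        assert sample_truncated_normal(rng, 5.0, 0.0) == 5.0

    def test_all_draws_nonnegative_under_heavy_truncation(self, rng):
        draws = [sample_truncated_normal(rng, 0.5, 1.0) for _ in range(500)]
        assert min(draws) >= 0.0


def fixture_like_params():
    p = default_parameters()
    p.transition_entries = {
        "mono": [("state_without_complications", "death", 0.05),
                 ("state_without_complications", "epilepsy", 0.02),
                 ("epilepsy", "death", 0.08)],
        "combo": [("state_without_complications", "death", 0.02),
                  ("state_without_complications", "epilepsy", 0.01),
                  ("epilepsy", "death", 0.05)],
    }
    return p


class TestSampleParameterSet:
    def test_zero_variance_returns_base(self, rng):
        p = fixture_like_params()
        s = sample_parameter_set(p, PSAConfig(se_fraction=0.0), rng)
        assert s.utilities == p.utilities
        assert s.imiglucerase == p.imiglucerase
        assert s.transition_entries == p.transition_entries

    def test_seeded_sampling_reproducible(self):
        p = fixture_like_params()
        cfg = PSAConfig(seed=42)
        a = sample_parameter_set(p, cfg, np.random.default_rng(42))
        b = sample_parameter_set(p, cfg, np.random.default_rng(42))
        assert a == b

    def test_sampled_values_respect_domains(self, rng):
        p = fixture_like_params()
        cfg = PSAConfig()
        for _ in range(200):
            s = sample_parameter_set(p, cfg, rng)
            for state in LIVE_STATES:
                assert 0.0 < s.utilities[state] < 1.0
            assert s.imiglucerase.pack_price > 0
            for key in ("mono", "combo"):
                m = s.transition_matrix(key)  # validates row-stochasticity
                assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-9)


class TestRunPSA:
    def test_single_zero_variance_draw_equals_base_case(self):
        p = fixture_like_params()
        base = run_base_case(p)
        draws = run_psa(p, PSAConfig(n_draws=1, se_fraction=0.0, seed=0))
        assert draws.loc[0, "cost_mono"] == pytest.approx(base.cost_mono)
        assert draws.loc[0, "qalys_combo"] == pytest.approx(base.qalys_combo)
        assert draws.loc[0, "incr_cost"] == pytest.approx(base.incr_cost)

    def test_seeded_runs_byte_identical(self):
        p = fixture_like_params()
        cfg = PSAConfig(n_draws=50, seed=7)
        a = run_psa(p, cfg).to_csv(index=False)
        b = run_psa(p, cfg).to_csv(index=False)
        assert a == b

    def test_mean_draws_near_deterministic_result(self):
        # central-limit check: PSA means sit within 3 MC standard errors
        p = fixture_like_params()
        base = run_base_case(p)
        draws = run_psa(p, PSAConfig(n_draws=400, seed=3))
        for col, target in (("incr_cost", base.incr_cost),
                            ("incr_qalys", base.incr_qalys)):
            x = draws[col]
            assert abs(x.mean() - target) < 3 * x.std(ddof=1) / np.sqrt(len(x))


class TestCEAC:
    def test_enumerated_example(self):
        draws = pd.DataFrame(
            {"incr_cost": [100.0, 300.0, 200.0], "incr_qalys": [1.0, 1.0, -1.0]}
        )
        curve = ceac(draws, np.array([150.0]))
        assert curve["prob_combo_ce"].iloc[0] == pytest.approx(1 / 3)

    def test_limits(self):
        draws = pd.DataFrame({"incr_cost": [10.0, 20.0], "incr_qalys": [0.5, 0.6]})
        assert ceac(draws, np.array([0.0]))["prob_combo_ce"].iloc[0] == 0.0
        assert ceac(draws, np.array([1e9]))["prob_combo_ce"].iloc[0] == 1.0

    def test_monotone_when_all_gains_positive(self):
        p = fixture_like_params()
        draws = run_psa(p, PSAConfig(n_draws=200, seed=5))
        assert (draws["incr_qalys"] > 0).all()
        curve = ceac(draws, np.linspace(0, 5e5, 40))
        assert (np.diff(curve["prob_combo_ce"]) >= 0).all()

    def test_reaches_one_above_maximum_icer(self):
        p = fixture_like_params()
        draws = run_psa(p, PSAConfig(n_draws=100, seed=6))
        max_icer = (draws["incr_cost"] / draws["incr_qalys"]).max()
        curve = ceac(draws, np.array([max_icer * 1.01]))
        assert curve["prob_combo_ce"].iloc[0] == 1.0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            ceac(pd.DataFrame({"incr_cost": [], "incr_qalys": []}), np.array([1.0]))


class TestCEPlane:
    def test_all_northeast(self):
        draws = pd.DataFrame({"incr_cost": [1.0, 2.0, 3.0], "incr_qalys": [0.1, 0.2, 0.3]})
        s = ce_plane_summary(draws)
        assert s.quadrants == {"NE": 3, "NW": 0, "SE": 0, "SW": 0}
        assert sum(s.quadrants.values()) == s.n_draws

    def test_isotropic_cloud_has_near_equal_axes(self, rng):
        xy = rng.normal(0.0, 1.0, size=(4000, 2))
        draws = pd.DataFrame({"incr_qalys": xy[:, 0], "incr_cost": xy[:, 1]})
        s = ce_plane_summary(draws)
        ratio = s.ellipse_axes[0] / s.ellipse_axes[1]
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_chi2_scaling_of_axes(self, rng):
        from scipy import stats

        xy = rng.normal(0.0, 2.0, size=(20_000, 2))
        draws = pd.DataFrame({"incr_qalys": xy[:, 0], "incr_cost": xy[:, 1]})
        s = ce_plane_summary(draws, confidence=0.95)
        expected = 2.0 * np.sqrt(stats.chi2.ppf(0.95, 2))
        assert s.ellipse_axes[0] == pytest.approx(expected, rel=0.05)

    def test_too_few_draws_rejected(self):
        draws = pd.DataFrame({"incr_cost": [1.0, 2.0], "incr_qalys": [0.1, 0.2]})
        with pytest.raises(ValueError):
            ce_plane_summary(draws)

    def test_degenerate_covariance_omits_ellipse(self):
        draws = pd.DataFrame({"incr_cost": [1.0] * 5, "incr_qalys": [0.1] * 5})
        s = ce_plane_summary(draws)
        assert s.ellipse_axes is None
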