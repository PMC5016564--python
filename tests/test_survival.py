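"""CJS likelihood correctness and hierarchical survival estimation."""

import datetime as dt
import math
import warnings

import numpy as np
import pytest
from scipy.special import expit

from bacips.design import EncounterHistory, SamplingOccasion, StudyDesign, classify_sessions
from bacips.diagnostics import RhatReport
from bacips.simulate import SimulationTruth, simulate_open_population
from bacips.survival import (
    CJSSurvival,
    PosteriorDraws,
    SurvivalParams,
    build_m_array,
    cjs_log_likelihood,
    fit_survival,
    shrinkage_estimates,
)
from bacips._cjs_mcmc import cjs_marray_loglik

from .oracles import all_histories, cjs_brute_force_likelihood


def _uniform_design(n_occasions: int, spacing: int = 91, base: float = 91.0) -> StudyDesign:
    occ = [
        SamplingOccasion(i, dt.date(2008, 1, 1) + dt.timedelta(days=spacing * i), "winter")
        for i in range(n_occasions)
    ]
    d = StudyDesign(
        occasions=occ,
        installation_date=occ[n_occasions // 2].date,
        base_period_days=base,
    )
    classify_sessions(d)
    return d


def _hist(detections, censored_after=None):
    return EncounterHistory("x", "treatment", "s1", detections, censored_after=censored_after)


class TestCjsLikelihood:
    def test_hand_product_for_full_detection_history(self, three_occasion_design):
        params = SurvivalParams(s=[0.8, 0.8], p=[0.5, 0.5])
        ll = cjs_log_likelihood(_hist((1, 1, 1)), params, three_occasion_design)
        assert ll == pytest.approx(math.log(0.8 * 0.5 * 0.8 * 0.5), abs=1e-12)

    def test_certain_survival_and_detection_give_probability_one(self, three_occasion_design):
        params = SurvivalParams(s=[1 - 1e-12] * 2, p=[1 - 1e-12] * 2)
        ll = cjs_log_likelihood(_hist((1, 1, 1)), params, three_occasion_design)
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_post_release_outcomes_sum_to_one(self, three_occasion_design):
        params = SurvivalParams(s=[0.7, 0.6], p=[0.4, 0.3])
        total = sum(
            math.exp(cjs_log_likelihood(_hist((1, a, b)), params, three_occasion_design))
            for a in (0, 1)
            for b in (0, 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n_occasions", [2, 3, 4])
    def test_matches_brute_force_enumeration(self, n_occasions):
        """Every detection pattern, censored and not, vs latent-state summation."""
        design = _uniform_design(n_occasions)
        rng = np.random.default_rng(n_occasions)
        T = n_occasions - 1
        for trial in range(3):
            params = SurvivalParams(s=rng.uniform(0.2, 0.9, T), p=rng.uniform(0.1, 0.9, T))
            e = np.array([iv.exponent for iv in design.intervals])
            s_eff = params.s**e
            for pattern in all_histories(n_occasions):
                ll = cjs_log_likelihood(_hist(pattern), params, design)
                brute = cjs_brute_force_likelihood(pattern, s_eff, params.p)
                assert ll == pytest.approx(math.log(brute), abs=1e-10)
                last = max(i for i, d in enumerate(pattern) if d)
                if last > pattern.index(1):
                    llc = cjs_log_likelihood(_hist(pattern, censored_after=last), params, design)
                    brutec = cjs_brute_force_likelihood(pattern, s_eff, params.p, censored_after=last)
                    assert llc == pytest.approx(math.log(brutec), abs=1e-10)

    def test_m_array_reduction_preserves_likelihood(self, desk_design):
        truth = SimulationTruth.from_design(desk_design, seed=5, emigration_prob=0.05)
        hist = [
            h
            for h in simulate_open_population(truth, 40, desk_design, seed=5)
            if h.watershed == "treatment"
        ]
        rng = np.random.default_rng(0)
        params = SurvivalParams(s=rng.uniform(0.3, 0.9, 12), p=rng.uniform(0.2, 0.8, 12))
        e = np.array([iv.exponent for iv in desk_design.intervals])
        ll_ind = cjs_log_likelihood(hist, params, desk_design)
        marr = build_m_array(hist, desk_design.n_intervals + 1)
        ll_marr = cjs_marray_loglik(marr, params.s**e, params.p)
        assert ll_marr == pytest.approx(ll_ind, rel=1e-12)

    def test_doubling_interval_equals_undetectable_intermediate_occasion(self):
        """A 182-day interval (exponent 2) is one 91-day interval walked twice."""
        long = _uniform_design(2, spacing=182)
        short = _uniform_design(3, spacing=91)
        s, p = 0.8, 0.4
        eps = 1e-12
        ll_long = cjs_log_likelihood(
            _hist((1, 1)), SurvivalParams(s=[s], p=[p]), long
        )
        ll_short = cjs_log_likelihood(
            _hist((1, 0, 1)), SurvivalParams(s=[s, s], p=[eps, p]), short
        )
        assert ll_long == pytest.approx(ll_short, abs=1e-10)

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            SurvivalParams(s=[1.0, 0.5], p=[0.5, 0.5])
        with pytest.raises(ValueError):
            SurvivalParams(s=[0.5], p=[0.0])

    def test_history_design_mismatch_rejected(self, three_occasion_design):
        params = SurvivalParams(s=[0.8, 0.8], p=[0.5, 0.5])
        with pytest.raises(ValueError, match="occasions"):
            cjs_log_likelihood(_hist((1, 1)), params, three_occasion_design)


class TestNuisancePrior:
    def test_back_transformed_percentiles_are_nearly_flat(self):
        rng = np.random.default_rng(42)
        theta = expit(rng.normal(0.0, 1.75, 200_000))
        lo, hi = np.percentile(theta, [2.5, 97.5])
        assert 0.01 < lo < 0.06
        assert 0.94 < hi < 0.99


class TestFitSurvival:
    def test_recovers_known_survival_at_large_n(self):
        # terminal S and p are confounded (only their product is identified),
        # so recovery is checked on the non-terminal intervals
        design = _uniform_design(4)
        truth = SimulationTruth(
            s_treatment=[0.7] * 3,
            s_control=[0.7] * 3,
            p_detect=[0.6] * 3,
            p_capture=0.3,
            n_site_period={},
            seed=1,
            interval_eras=[iv.era for iv in design.intervals],
        )
        hist = [
            h
            for h in simulate_open_population(truth, 2000, design, seed=1)
            if h.watershed == "treatment"
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_survival(
                hist, design, chains=4, iters_per_chain=1000, burn=500, thin=2, seed=10
            )
        med = np.median(draws.s_flat(), axis=0)
        assert np.all(np.abs(med[:-1] - 0.7) < 0.05)
        p_med = np.median(draws.p.reshape(-1, 3), axis=0)
        assert np.all(np.abs(p_med[:-1] - 0.6) < 0.05)

    def test_identical_strata_give_overlapping_hypermeans(self, desk_design):
        truth = SimulationTruth.from_design(
            desk_design, k_s=1.0, treatment_offset=1.0, seed=2, emigration_prob=0.0
        )
        hist = [
            h
            for h in simulate_open_population(truth, 400, desk_design, seed=2)
            if h.watershed == "control"
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = CJSSurvival(chains=4, iters=1000, burn=500, thin=2, seed=3).fit(
                hist, desk_design
            )
        mu = est.draws_.mu.reshape(-1, 2)
        lo_b, hi_b = np.percentile(mu[:, 0], [2.5, 97.5])
        lo_a, hi_a = np.percentile(mu[:, 1], [2.5, 97.5])
        assert max(lo_b, lo_a) < min(hi_b, hi_a)  # intervals overlap

    def test_zero_release_interval_is_prior_dominated(self, desk_design):
        truth = SimulationTruth.from_design(desk_design, seed=4, emigration_prob=0.0)
        hist = [
            h
            for h in simulate_open_population(truth, 200, desk_design, seed=4)
            if h.watershed == "treatment" and h.first_detection >= 1
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = fit_survival(
                hist, desk_design, chains=4, iters_per_chain=800, burn=500, thin=2, seed=5
            )
        s = draws.s_flat()
        # no releases inform interval 0; its posterior should be far wider
        # than a data-informed interval's, not degenerate
        assert s[:, 0].std() > 2 * s[:, 1].std()

    def test_mixed_watersheds_rejected(self, desk_design):
        truth = SimulationTruth.from_design(desk_design, seed=6)
        hist = simulate_open_population(truth, 10, desk_design, seed=6)
        with pytest.raises(ValueError, match="separately"):
            CJSSurvival(chains=2, iters=10, burn=10, thin=1, seed=0).fit(hist, desk_design)


class TestShrinkageEstimates:
    def _draws(self, s_values: np.ndarray) -> PosteriorDraws:
        n = s_values.shape[0]
        shape3 = (1, n, 1)
        return PosteriorDraws(
            s=s_values.reshape(shape3),
            p=np.full(shape3, 0.5),
            mu=np.zeros(shape3),
            sigma=np.ones(shape3),
            interval_eras=["before"],
            strata=["before"],
            rhat=RhatReport({}),
        )

    def test_logit_zero_draws_give_median_half(self):
        out = shrinkage_estimates(self._draws(np.full(100, 0.5)))
        assert out.loc[0, "median"] == pytest.approx(0.5)

    def test_quantiles_commute_with_inverse_logit(self):
        rng = np.random.default_rng(0)
        logits = 1.0 + rng.normal(size=20001) * 0.5
        logits = np.concatenate([logits, 2.0 - logits])  # exactly symmetric about 1
        out = shrinkage_estimates(self._draws(expit(logits)))
        assert out.loc[0, "median"] == pytest.approx(expit(1.0), abs=1e-6)

    def test_percentile_ordering(self):
        rng = np.random.default_rng(1)
        out = shrinkage_estimates(self._draws(rng.uniform(0.01, 0.99, 500)))
        assert out.loc[0, "q2.5"] <= out.loc[0, "median"] <= out.loc[0, "q97.5"]

    def test_empty_draws_rejected(self):
        empty = self._draws(np.empty(0))
        with pytest.raises(ValueError):
            shrinkage_estimates(empty)
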