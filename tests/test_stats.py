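"""Wilcoxon, mixed-model fitting/selection, recovery and feasibility tests.

The exact Wilcoxon path is validated against literal brute-force enumeration
of all 2^n sign assignments; the approximate path against scipy's
implementation on tie-free data.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from emibandit import (
    EventLog,
    LmmGenParams,
    LmmSpec,
    ReviewEvent,
    SimParams,
    SpecificationError,
    fit_lmm,
    generate_lmm_dataset,
    recover_parameters,
    select_model_aic,
    simulate_cohort,
    summarize_feasibility,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided exact p by enumerating every sign assignment of the ranks."""
    d = d[d != 0]
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "degenerate"
        assert res.p_value == 1.0
        assert res.n_effective == 0

    def test_six_concordant_pairs(self):
        res = wilcoxon_signed_rank([0.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = np.round(rng.normal(0.3, 1.0, size=n), 1)  # rounding induces ties
        res = wilcoxon_signed_rank(np.zeros(n), d, mode="exact")
        if res.method == "degenerate":
            assert not np.any(d != 0)
            return
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(-9, 9), min_size=2, max_size=10))
    def test_exact_matches_brute_force_property(self, diffs):
        d = np.asarray(diffs, dtype=float)
        res = wilcoxon_signed_rank(np.zeros_like(d), d, mode="exact")
        if res.method == "degenerate":
            assert not np.any(d != 0)
        else:
            assert res.p_value == pytest.approx(
                brute_force_signed_rank_p(d), abs=1e-12
            )

    def test_approx_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(0)
        pre = rng.normal(size=30)
        post = pre + rng.normal(0.3, 1.0, size=30)
        res = wilcoxon_signed_rank(pre, post, mode="approx")
        ref = scipy.stats.wilcoxon(post, pre, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auto_switches_to_approx_for_large_or_tied(self):
        rng = np.random.default_rng(1)
        big = rng.normal(size=30)
        assert wilcoxon_signed_rank(np.zeros(30), big).method == "approx"
        tied = np.array([1.0, 1.0, -1.0, 2.0])
        assert wilcoxon_signed_rank(np.zeros(4), tied).method == "approx"
        assert wilcoxon_signed_rank(np.zeros(4), tied, mode="exact").method == "exact"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [2.0])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0], mode="bayes")


NOISE_FREE = LmmGenParams(
    sd_zeta0=0.0, sd_zeta1=0.0, sd_eps=0.0, psych_prob=0.5, seed=0
)
FIXED_ONLY_SPEC = LmmSpec(
    level1_fixed=("depression",),
    level2_fixed=("psych_comorbidity",),
    cross_level_interactions=(("depression", "psych_comorbidity"),),
    random_effects=(),
)


class TestFitLmm:
    def test_noise_free_recovers_generating_values_exactly(self):
        df = generate_lmm_dataset(NOISE_FREE)
        fit = fit_lmm(df, FIXED_ONLY_SPEC)
        assert fit.coef("intercept") == pytest.approx(4.45, abs=1e-6)
        assert fit.coef("depression") == pytest.approx(-1.88, abs=1e-6)
        assert fit.coef("depression:psych_comorbidity") == pytest.approx(1.59, abs=1e-6)

    def test_row_order_and_user_label_invariance(self):
        df = generate_lmm_dataset(LmmGenParams(seed=5))
        fit1 = fit_lmm(df, LmmSpec())
        shuffled = df.sample(frac=1.0, random_state=0)
        shuffled["user_id"] = shuffled["user_id"].map(lambda u: f"Z-{u}")
        fit2 = fit_lmm(shuffled, LmmSpec())
        pd.testing.assert_frame_equal(
            fit1.fixed_effects, fit2.fixed_effects, atol=1e-6, rtol=1e-5
        )

    def test_rank_deficiency_names_collinear_columns(self):
        df = generate_lmm_dataset(LmmGenParams(seed=6))
        df["anxiety"] = df["depression"] * 2.0
        spec = LmmSpec(level1_fixed=("depression", "anxiety"), level2_fixed=(),
                       cross_level_interactions=(), random_effects=("intercept",))
        with pytest.raises(SpecificationError, match="anxiety|depression"):
            fit_lmm(df, spec)

    def test_single_participant_random_effects_flagged(self):
        df = generate_lmm_dataset(
            LmmGenParams(n_participants=1, obs_per_participant=8, seed=7)
        )
        try:
            fit = fit_lmm(df, LmmSpec(level2_fixed=(), cross_level_interactions=()))
            assert not fit.converged
        except SpecificationError:
            pass  # equally acceptable: inestimable structure reported loudly

    def test_missing_covariates_dropped_complete_case(self):
        df = generate_lmm_dataset(LmmGenParams(seed=8))
        df.loc[df.index[:10], "depression"] = np.nan
        fit = fit_lmm(df, LmmSpec())
        assert fit.n_dropped == 10
        assert fit.n_obs == len(df) - 10

    def test_aic_prefers_true_effect(self):
        """Adding a genuinely nonzero depression effect lowers AIC."""
        df = generate_lmm_dataset(LmmGenParams(gamma11=0.0, seed=9))
        with_dep = fit_lmm(df, LmmSpec(
            level1_fixed=("depression",), level2_fixed=(),
            cross_level_interactions=(), random_effects=("intercept",),
        ))
        without = fit_lmm(df, LmmSpec(
            level1_fixed=(), level2_fixed=(),
            cross_level_interactions=(), random_effects=("intercept",),
        ))
        assert with_dep.aic < without.aic

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LmmSpec(level1_fixed=("bmi",))
        with pytest.raises(ValueError):
            LmmSpec(level1_fixed=(), cross_level_interactions=(("depression", "sex"),))
        with pytest.raises(ValueError):
            LmmSpec(level1_fixed=("week",), random_effects=("depression_slope",))


class TestModelSelection:
    CANDIDATE_L1 = ("depression", "week")
    CANDIDATE_L2 = ("psych_comorbidity",)
    CANDIDATE_RAND = (("intercept",),)

    def test_true_depression_effect_is_selected(self):
        df = generate_lmm_dataset(
            LmmGenParams(sd_zeta1=0.0, gamma11=0.0, seed=10)
        )
        best, ranking = select_model_aic(
            df, self.CANDIDATE_L1, self.CANDIDATE_L2, self.CANDIDATE_RAND
        )
        assert "depression" in best.level1_fixed
        assert ranking["aic"].is_monotonic_increasing

    def test_null_data_prefers_intercept_only_in_plurality(self):
        """Over replicates of pure-noise data, the intercept-only fixed
        structure is the modal AIC winner (any single replicate may pick up
        a spurious term)."""
        winners = []
        for seed in range(12):
            df = generate_lmm_dataset(
                LmmGenParams(gamma10=0.0, gamma11=0.0, sd_zeta1=0.0, seed=100 + seed)
            )
            best, _ = select_model_aic(
                df, self.CANDIDATE_L1, self.CANDIDATE_L2, self.CANDIDATE_RAND
            )
            winners.append(best.level1_fixed + best.level2_fixed)
        counts = {w: winners.count(w) for w in set(winners)}
        assert max(counts, key=counts.get) == ()

    def test_tie_breaks_deterministically(self):
        df = generate_lmm_dataset(LmmGenParams(seed=12))
        best1, rank1 = select_model_aic(
            df, ("depression",), (), self.CANDIDATE_RAND, ()
        )
        best2, rank2 = select_model_aic(
            df, ("depression",), (), self.CANDIDATE_RAND, ()
        )
        assert best1 == best2
        pd.testing.assert_frame_equal(rank1, rank2)


class TestRecovery:
    def test_noise_free_bias_is_zero(self):
        rep = recover_parameters(NOISE_FREE, FIXED_ONLY_SPEC, n_reps=3, seed=0)
        assert np.allclose(rep.per_coefficient["bias"], 0.0, atol=1e-6)

    def test_same_seed_identical_reports(self):
        a = recover_parameters(LmmGenParams(), LmmSpec(), n_reps=5, seed=1)
        b = recover_parameters(LmmGenParams(), LmmSpec(), n_reps=5, seed=1)
        pd.testing.assert_frame_equal(a.per_coefficient, b.per_coefficient)
        assert a.n_converged == b.n_converged

    def test_reports_convergence_accounting(self):
        rep = recover_parameters(LmmGenParams(), LmmSpec(), n_reps=5, seed=2)
        assert rep.n_converged <= rep.n_reps
        assert set(rep.per_coefficient.index) == {
            "intercept", "depression", "depression:psych_comorbidity",
        }


class TestFeasibility:
    def _log_with_rates(self, days_per_user):
        from datetime import datetime, timedelta, timezone

        t0 = datetime(2024, 1, 1, 20, 0, tzinfo=timezone.utc)
        log = EventLog()
        for uid, n_days in days_per_user.items():
            log.users[uid] = {"timezone": "UTC"}
            for d in range(n_days):
                log.events.append(
                    ReviewEvent(uid, t0 + timedelta(days=d), {"A": True}, ())
                )
        return log

    def test_three_user_summary(self):
        # 80 / 90 / 100 percent of 10 scheduled days
        report = summarize_feasibility(
            self._log_with_rates({"a": 8, "b": 9, "c": 10}), scheduled_days=10
        )
        assert report.median == 90.0
        assert (report.min, report.max) == (80.0, 100.0)
        assert report.mean == pytest.approx(90.0)

    def test_even_sample_median_is_midpoint(self):
        report = summarize_feasibility(
            self._log_with_rates({"a": 6, "b": 8, "c": 9, "d": 10}), 10
        )
        assert report.median == pytest.approx(85.0)

    def test_single_user_sd_flagged(self):
        report = summarize_feasibility(self._log_with_rates({"a": 9}), 10)
        assert report.median == report.mean == 90.0
        assert report.sd is None

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            summarize_feasibility(EventLog())

    def test_simulated_cohort_without_missingness(self):
        log = simulate_cohort(
            SimParams(n_participants=3, n_days=10, missing_review_prob=0.0, seed=3)
        )
        report = summarize_feasibility(log, scheduled_days=10)
        assert report.median == 100.0
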