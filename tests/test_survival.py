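import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_two_group

from iciscope.io import ClinicalTable
from iciscope.simulate import simulate_survival
from iciscope.survival import (
    best_cutoff,
    cox_hr,
    kaplan_meier,
    km_by_group,
    logrank_test,
    stratified_forest,
)
from iciscope.survival import _breslow_loglik, _logrank_z


def km_oracle(times, events):
    """Brute-force product-limit over risk sets, independent of lifelines."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    grid = np.unique(times)
    surv = []
    s = 1.0
    for t in grid:
        n_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n_risk
        surv.append(s)
    return grid, np.array(surv)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0], atol=1e-12)
        np.testing.assert_array_equal(curve.times, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_stays_at_one(self):
        curve = kaplan_meier([5.0, 7.0, 9.0], [0, 0, 0])
        np.testing.assert_allclose(curve.survival, 1.0)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(2)
        times = rng.integers(1, 8, size=20).astype(float)  # heavy ties
        events = rng.integers(0, 2, size=20)
        curve = kaplan_meier(times, events)
        grid, surv = km_oracle(times, events)
        np.testing.assert_allclose(curve.survival, surv, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier([], [])


class TestLogrank:
    def test_duplicated_data_gives_zero_statistic(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 0, 1, 1, 0, 1]
        groups = ["a", "a", "a", "b", "b", "b"]
        chi2, p = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_identical_groups_zero(self):
        times = [1.0, 2.0] * 3
        events = [1, 1] * 3
        groups = ["a"] * 2 + ["b"] * 2 + ["c"] * 2
        chi2, _ = logrank_test(times, events, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_power_against_hazard_ratio_three(self):
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t1 = rng.exponential(1.0, size=200)
            t2 = rng.exponential(3.0, size=200)
            times = np.r_[t1, t2]
            events = np.ones(400, int)
            groups = ["a"] * 200 + ["b"] * 200
            _, p = logrank_test(times, events, groups)
            hits += p < 1e-4
        assert hits >= 19

    def test_monotone_time_transform_invariance(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(1.0, size=60)
        events = rng.integers(0, 2, size=60)
        groups = rng.choice(["a", "b"], size=60)
        chi2_a, _ = logrank_test(times, events, groups)
        chi2_b, _ = logrank_test(np.exp(times), events, groups)
        assert chi2_a == pytest.approx(chi2_b, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestBestCutoff:
    def test_constant_score_no_admissible_split(self):
        with pytest.raises(ValueError):
            best_cutoff(np.ones(20), np.arange(1, 21.0), np.ones(20, int))

    def test_matches_exhaustive_two_group_search(self):
        # oracle: |z| = sqrt(chi2) from lifelines' two-group log-rank at
        # every admissible midpoint
        rng = np.random.default_rng(5)
        n = 30
        score = rng.normal(size=n)
        times = rng.exponential(np.where(score > 0.3, 0.5, 1.5))
        events = rng.integers(0, 2, size=n)
        res = best_cutoff(score, times, events, min_group_fraction=0.1)
        distinct = np.unique(score)
        best_abs, best_c = -1.0, None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            high = score > c
            if high.sum() < 3 or (~high).sum() < 3:
                continue
            r = ll_two_group(times[high], times[~high], events[high], events[~high])
            z = np.sqrt(r.test_statistic)
            if z > best_abs + 1e-12:
                best_abs, best_c = z, c
        assert res.cutoff == pytest.approx(best_c)
        assert abs(res.z_statistic) == pytest.approx(best_abs, rel=1e-9)

    def test_planted_change_point_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            score = rng.normal(size=400)
            lam = np.where(score > 0.0, 2.0, 1.0)  # hazard doubles above 0
            times = rng.exponential(1.0 / lam)
            events = np.ones(400, int)
            res = best_cutoff(score, times, events)
            lo, hi = np.quantile(score, [0.4, 0.6])
            hits += lo <= res.cutoff <= hi
        assert hits >= 8

    def test_standardized_statistic_matches_chi2(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(1.0, size=40)
        events = np.ones(40, int)
        in_group = rng.random(40) > 0.5
        z = _logrank_z(times, events, in_group)
        r = ll_two_group(times[in_group], times[~in_group],
                         events[in_group], events[~in_group])
        assert z**2 == pytest.approx(r.test_statistic, rel=1e-9)


class TestCoxHR:
    def test_identical_groups_hr_one(self):
        times = np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)]
        events = np.ones(20, int)
        x = np.r_[np.zeros(10), np.ones(10)]
        res = cox_hr(times, events, x)
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_of_partial_likelihood(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(1.0, size=10)
        events = np.ones(10, int)
        x = rng.integers(0, 2, size=10).astype(float)
        res = cox_hr(times, events, x)
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [_breslow_loglik(b, times, events, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert np.log(res.hazard_ratio) == pytest.approx(beta_grid, abs=1e-4)

    def test_agrees_with_lifelines_on_untied_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 80
        x = rng.integers(0, 2, size=n).astype(float)
        times = rng.exponential(np.exp(-0.8 * x))
        events = rng.integers(0, 2, size=n)
        events[0] = 1
        res = cox_hr(times, events, x)
        df = pd.DataFrame({"t": times, "e": events, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.log(res.hazard_ratio) == pytest.approx(
            cph.params_["x"], abs=1e-6
        )

    def test_monotone_likelihood_flagged(self):
        times = np.arange(1.0, 11.0)
        events = np.r_[np.ones(5, int), np.zeros(5, int)]
        x = np.r_[np.ones(5), np.zeros(5)]  # all events in group 1
        res = cox_hr(times, events, x)
        assert res.monotone_likelihood
        assert res.ci_high == np.inf

    def test_km_and_cox_agree_in_direction(self):
        rng = np.random.default_rng(9)
        x = np.r_[np.zeros(100), np.ones(100)]
        times = rng.exponential(np.where(x == 1, 0.4, 1.0))
        events = np.ones(200, int)
        res = cox_hr(times, events, x)
        assert res.hazard_ratio > 1
        clin = ClinicalTable(
            pd.DataFrame(
                {"os_time": times, "os_event": events},
                index=[f"s{i}" for i in range(200)],
            )
        )
        groups = pd.Series(np.where(x == 1, "high", "low"), index=clin.data.index)
        curves = km_by_group(clin, groups)
        grid = np.linspace(0.05, 1.0, 10)
        s_high = np.interp(grid, curves["high"].times, curves["high"].survival)
        s_low = np.interp(grid, curves["low"].times, curves["low"].survival)
        assert (s_high <= s_low + 1e-9).all()


class TestStratifiedForest:
    @staticmethod
    def _cohort(seed, n=300):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(n)]
        group = pd.Series(rng.choice(["high", "low"], size=n), index=idx)
        score = (group == "high").astype(float)
        clin = simulate_survival(
            score, baseline_hazard=0.02, log_hr_per_unit=-0.7,
            censor_rate=0.2, seed=seed,
        )
        clin.data["sex"] = rng.choice(["m", "f"], size=n)
        return clin, group

    def test_whole_cohort_stratum_equals_unstratified(self):
        clin, group = self._cohort(0)
        strata = {"all": pd.Series(True, index=clin.data.index)}
        out = stratified_forest(clin, group, strata)
        direct = cox_hr(
            clin.data["os_time"], clin.data["os_event"],
            (group == "high").astype(float).to_numpy(),
        )
        assert out[0].hazard_ratio == pytest.approx(direct.hazard_ratio, rel=1e-9)

    def test_empty_stratum_absent_from_output(self):
        clin, group = self._cohort(1)
        strata = {
            "none": pd.Series(False, index=clin.data.index),
            "all": pd.Series(True, index=clin.data.index),
        }
        out = stratified_forest(clin, group, strata)
        assert [r.stratum for r in out] == ["all"]

    def test_uniform_effect_covered_by_stratum_cis(self):
        # effect is identical in every stratum; stratum CIs should cover the
        # planted HR at roughly the nominal rate
        covered = total = 0
        for seed in range(5):
            clin, group = self._cohort(seed)
            strata = {
                "male": clin.data["sex"] == "m",
                "female": clin.data["sex"] == "f",
            }
            for res in stratified_forest(clin, group, strata):
                total += 1
                covered += res.ci_low <= np.exp(-0.7) <= res.ci_high
        assert covered >= total - 1
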