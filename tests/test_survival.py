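import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from isend.survival import (
    NOT_REACHED,
    cox_ph,
    kaplan_meier,
    log_rank,
    median_survival,
    reverse_km_followup,
)


class TestKaplanMeier:
    def test_no_censoring_equals_one_minus_ecdf(self):
        curve = kaplan_meier([1, 2, 3, 4, 5], [1] * 5)
        assert np.allclose(curve.survival, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert median_survival(curve).median == 3

    def test_hand_product_limit_with_censoring(self):
        # {1, 2+, 3}: S = 2/3 after t=1, then 2/3 * (1 - 1/1) = 0 after t=3
        curve = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert np.allclose(curve.event_times, [1, 3])
        assert np.allclose(curve.survival, [2 / 3, 0.0])
        assert list(curve.at_risk) == [3, 1] and list(curve.events) == [1, 1]

    def test_all_censored_is_flat_one(self):
        curve = kaplan_meier([1, 2], [0, 0])
        assert curve.event_times.size == 0 and curve.n_events == 0
        assert median_survival(curve).median == NOT_REACHED

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            kaplan_meier([], [])

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=1000), min_size=1,
                    max_size=30))
    def test_km_is_ecdf_complement_without_censoring(self, times):
        """With zero censoring the product-limit estimate is exactly
        1 − (empirical CDF of the event times)."""
        times = np.round(np.asarray(times), 6)  # induce occasional ties
        curve = kaplan_meier(times, np.ones(times.size, int))
        for t in np.unique(times):
            ecdf = np.mean(times <= t)
            assert curve.survival_at(t) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_greenwood_variance_zero_before_first_event_and_band_contains_s(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(5, 200)
        e = (rng.random(200) < 0.7).astype(int)
        curve = kaplan_meier(t, e)
        assert curve.survival_at(float(curve.event_times[0]) / 2) == 1.0
        # cumulative-hazard-scale variance sum is non-decreasing
        ratio = curve.greenwood_var / np.maximum(curve.survival, 1e-300) ** 2
        finite = np.isfinite(ratio)
        assert np.all(np.diff(ratio[finite]) >= -1e-12)
        lower, upper = curve.confidence_band()
        assert np.all(lower - 1e-12 <= curve.survival)
        assert np.all(curve.survival <= upper + 1e-12)


class TestMedianSurvival:
    def test_curve_never_below_half_is_not_reached(self):
        curve = kaplan_meier([1, 2, 3, 4, 5], [1, 1, 0, 0, 0])  # min S = 0.6
        assert np.min(curve.survival) == pytest.approx(0.6)
        assert median_survival(curve).median == NOT_REACHED

    def test_ci_brackets_median(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(10, 500)
        cens = rng.uniform(5, 40, 500)
        curve = kaplan_meier(np.minimum(t, cens), (t <= cens).astype(int))
        est = median_survival(curve)
        assert est.ci_lower <= est.median <= est.ci_upper

    def test_recovers_generating_median(self):
        """Exponential median 4.5 months, n=5000, 20% independent censoring."""
        rng = np.random.default_rng(42)
        n = 5000
        t_true = rng.exponential(4.5 / np.log(2), n)
        cens = rng.exponential(4.5 / np.log(2) * 4.4, n)  # ~20% censored
        t, e = np.minimum(t_true, cens), (t_true <= cens).astype(int)
        assert 0.1 < 1 - e.mean() < 0.3
        est = median_survival(kaplan_meier(t, e))
        assert 4.2 <= est.median <= 4.8


class TestReverseKM:
    def test_no_censoring_followup_not_reached(self):
        assert reverse_km_followup([1, 2, 3], [1, 1, 1]).median == NOT_REACHED

    def test_all_censored_is_plain_km_median(self):
        assert reverse_km_followup([1, 2, 3], [0, 0, 0]).median == 2

    def test_recovers_administrative_followup(self):
        """Uniform(12, 24)-month administrative censoring with rare events
        has known median potential follow-up 18 months."""
        rng = np.random.default_rng(11)
        n = 4000
        t_true = rng.exponential(400, n)  # rare events
        cens = rng.uniform(12, 24, n)
        t, e = np.minimum(t_true, cens), (t_true <= cens).astype(int)
        est = reverse_km_followup(t, e)
        assert est.ci_lower <= 18 <= est.ci_upper
        assert est.median == pytest.approx(18, abs=0.75)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = ([1, 2, 3, 4], [1, 1, 0, 1])
        res = log_rank([g, g])
        assert res.statistic == pytest.approx(0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="zero observations"):
            log_rank([([1, 2], [1, 1]), ([], [])])

    @pytest.mark.parametrize("group_a, group_b, tol", [
        ([1, 3, 5, 7], [2, 4, 6, 8], 0.1),
        ([1, 2, 3, 4], [5, 6, 7, 8], 0.1),
    ])
    def test_agrees_with_exhaustive_permutation_oracle(self, group_a, group_b, tol):
        """The chi-square p agrees with the exact permutation-of-labels null
        within the asymptotic-vs-exact discrepancy expected at n=8 (the
        chi-square approximation is coarse at this size; tolerance 0.1)."""
        events = np.ones(8, int)
        times = np.array(group_a + group_b, float)
        observed = log_rank([(group_a, [1] * 4), (group_b, [1] * 4)])
        perm_stats = []
        for combo in itertools.combinations(range(8), 4):
            in_a = np.zeros(8, bool)
            in_a[list(combo)] = True
            perm_stats.append(log_rank([
                (times[in_a], events[in_a]), (times[~in_a], events[~in_a])
            ]).statistic)
        p_exact = np.mean(np.asarray(perm_stats) >= observed.statistic - 1e-9)
        assert observed.p_value == pytest.approx(p_exact, abs=tol)

    def test_power_at_group_separation(self):
        """Three exponential groups with medians 23/13.4/4.5 at n=150/group
        are separated essentially surely."""
        rng = np.random.default_rng(21)
        groups = []
        for med in (23.0, 13.4, 4.5):
            t_true = rng.exponential(med / np.log(2), 150)
            cens = rng.uniform(10, 26, 150)
            groups.append((np.minimum(t_true, cens), (t_true <= cens).astype(int)))
        res = log_rank(groups)
        assert res.df == 2
        assert res.p_value < 1e-4
        assert res.p_display() == "< 0.0001"

    def test_invariant_to_relabeling_and_time_shift(self):
        rng = np.random.default_rng(4)
        groups = []
        for _ in range(3):
            t = rng.exponential(5, 40)
            e = (rng.random(40) < 0.8).astype(int)
            groups.append((t, e))
        base = log_rank(groups)
        relabeled = log_rank(groups[::-1])
        shifted = log_rank([(t + 7.5, e) for t, e in groups])
        assert relabeled.statistic == pytest.approx(base.statistic)
        assert shifted.statistic == pytest.approx(base.statistic)


class TestCox:
    TOY = dict(times=[1, 4, 6, 8, 9, 10], events=[1, 1, 1, 1, 1, 1],
               x=np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0]))

    def test_single_covariate_matches_brute_force_partial_likelihood(self):
        """On a 6-patient tie-free dataset the fitted coefficient matches a
        direct maximiser of the written-out partial likelihood to 1e-4."""
        fit = cox_ph(pd.DataFrame({"x": self.TOY["x"]}),
                     self.TOY["times"], self.TOY["events"])
        order = np.argsort(self.TOY["times"])
        xs = self.TOY["x"][order]

        def neg_partial_loglik(beta):
            ll = 0.0
            for i in range(xs.size):
                ll += beta * xs[i] - np.log(np.sum(np.exp(beta * xs[i:])))
            return -ll

        brute = minimize_scalar(neg_partial_loglik, bounds=(-5, 5),
                                method="bounded", options={"xatol": 1e-10})
        assert fit.converged
        assert fit.summary["coef"].iloc[0] == pytest.approx(brute.x, abs=1e-4)
        # ascent property: fitted partial likelihood beats the null model
        assert -neg_partial_loglik(fit.summary["coef"].iloc[0]) >= -neg_partial_loglik(0.0)

    def test_constant_covariate_rejected_or_null(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 40)
        e = np.ones(40, int)
        X = pd.DataFrame({"z": np.zeros(40), "x": rng.random(40)})
        fit = cox_ph(X, t, e)
        if fit.converged and "z" in fit.summary.index:
            assert fit.summary.loc["z", "hr"] == pytest.approx(1.0, abs=1e-6)

    def test_hr_ci_consistency(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        t_true = rng.exponential(10 / np.log(2) / np.exp(0.5 * x))
        cens = rng.uniform(5, 30, n)
        fit = cox_ph(pd.DataFrame({"x": x}), np.minimum(t_true, cens),
                     (t_true <= cens).astype(int))
        row = fit.summary.loc["x"]
        assert row["hr"] == pytest.approx(np.exp(row["coef"]), rel=1e-9)
        assert row["ci_lower"] == pytest.approx(
            np.exp(row["coef"] - 1.959964 * row["se"]), rel=1e-6)
        assert row["ci_upper"] == pytest.approx(
            np.exp(row["coef"] + 1.959964 * row["se"]), rel=1e-6)

    def test_recovers_generating_hazard_ratios(self):
        """Three independent binary covariates with true HRs {1.2, 1.8, 1.8}
        on exponential data, n=5000: estimates within ±0.15 of truth."""
        rng = np.random.default_rng(77)
        n = 5000
        X = pd.DataFrame({
            "male": rng.integers(0, 2, n).astype(float),
            "ecog_2plus": (rng.random(n) < 0.2).astype(float),
            "composite": (rng.random(n) < 0.17).astype(float),
        })
        true_hr = {"male": 1.2, "ecog_2plus": 1.8, "composite": 1.8}
        lam = (np.log(2) / 13.0) * np.prod(
            [true_hr[c] ** X[c].to_numpy() for c in X], axis=0)
        t_true = rng.exponential(1 / lam)
        cens = rng.uniform(10, 26, n)
        fit = cox_ph(X, np.minimum(t_true, cens), (t_true <= cens).astype(int))
        assert fit.converged
        for cov, hr in true_hr.items():
            assert fit.summary.loc[cov, "hr"] == pytest.approx(hr, abs=0.15)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            cox_ph(pd.DataFrame({"x": [1.0, 0.0]}), [1, 2], [0, 0])
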