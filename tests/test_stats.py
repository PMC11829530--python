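import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from saccadekit.scoring import OUTCOME_FAMILY
from saccadekit.simulate import simulate_outcome_rows
from saccadekit.stats import (
    PowerSpec,
    ancova_group_effect,
    bh_adjust,
    choose_test,
    cohens_d,
    compare_groups,
    lda_classify,
    mahalanobis_outliers,
    mann_whitney_u,
    pearson_exploratory,
    power_pearson,
    power_twosample_t,
    required_n_ttest,
)


# ---------------------------------------------------------------------------
# oracles


def mwu_permutation_p(a, b):
    """Exhaustive-permutation two-sided Mann-Whitney p (tie-free data)."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    mid = n1 * len(b) / 2.0

    def u_stat(idx):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        return sum(np.sum(xi > y) for xi in x)

    obs = abs(u_stat(range(n1)) - mid)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mid) >= obs - 1e-12:
            count += 1
    return count / total


def bh_stepup_adjusted(p):
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------


class TestChooseTest:
    def test_gaussian_samples_mostly_student_t(self):
        picks = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            picks.append(choose_test(rng.normal(0, 1, 25), rng.normal(0, 1, 25)))
        # both-group Shapiro pass probability is 0.95^2 ~ 0.90
        assert np.mean([p == "student_t" for p in picks]) >= 0.85

    def test_skewed_sample_goes_nonparametric(self):
        picks = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            picks.append(choose_test(rng.normal(0, 1, 25),
                                     rng.lognormal(0, 1, 25)))
        assert np.mean([p == "mann_whitney_u" for p in picks]) >= 0.95

    def test_zero_variance_in_both_groups_skipped(self):
        assert choose_test([0.0] * 10, [0.0] * 12) == "skipped_zero_variance"

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMannWhitney:
    def test_complete_separation(self):
        u, p, rb = mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert u == 9.0 and rb == 1.0

    def test_identical_samples_near_zero_effect(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.permutation(a)
        _, _, rb = mann_whitney_u(a, b)
        assert abs(rb) < 1e-12

    def test_sign_convention_matches_reported_tables(self):
        # first group stochastically smaller => negative rank-biserial
        _, _, rb = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert rb == -1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_permutation_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 7)
        b = rng.normal(0.5, 1, 8)
        _, p, _ = mann_whitney_u(a, b)
        assert p == pytest.approx(mwu_permutation_p(a, b), abs=1e-9)


class TestBenjaminiHochberg:
    def test_matches_stepup_bruteforce_on_arithmetic_grid(self):
        p = np.arange(1, 24) / 100.0  # 0.01 .. 0.23, m = 23
        assert np.allclose(bh_adjust(p), bh_stepup_adjusted(p), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_stepup_bruteforce_random(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 23)
        assert np.allclose(bh_adjust(p), bh_stepup_adjusted(p), atol=1e-12)

    def test_adjusted_monotone_in_rank_and_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 40)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_fdr_controlled_on_independent_pvalues(self):
        """Empirical FDR stays below q + 0.02 with 23 hypotheses of
        which 5 carry true effects."""
        rng = np.random.default_rng(0)
        q, reps = 0.05, 1000
        fdp = []
        for _ in range(reps):
            z = rng.normal(0, 1, 23)
            z[:5] += 3.5  # true effects
            p = 2 * sps.norm.sf(np.abs(z))
            rej = bh_adjust(p) <= q
            v = np.sum(rej[5:])
            fdp.append(v / max(np.sum(rej), 1))
        assert np.mean(fdp) <= q + 0.02


class TestCompareGroups:
    def test_family_is_23_outcomes(self, rng):
        rows = simulate_outcome_rows(26, 26, rng)
        res = compare_groups(rows)
        assert len(res) == 23
        assert [r.outcome_name for r in res] == OUTCOME_FAMILY

    def test_missing_column_rejected_by_name(self, rng):
        rows = simulate_outcome_rows(10, 10, rng).drop(columns=["anti_gain"])
        with pytest.raises(ValueError, match="anti_gain"):
            compare_groups(rows)

    def test_skipped_outcomes_not_tested_but_listed(self, rng):
        rows = simulate_outcome_rows(20, 20, rng)
        rows["mg_inhibitory_5"] = 0.0
        res = {r.outcome_name: r for r in compare_groups(rows)}
        sk = res["mg_inhibitory_5"]
        assert sk.test == "skipped_zero_variance"
        assert np.isnan(sk.p_raw)

    def test_cohens_d_sign_control_minus_subclinical(self, rng):
        rows = simulate_outcome_rows(26, 26, rng)
        rows.loc[rows.group == "subclinical", "pro_gain"] += 5.0
        res = {r.outcome_name: r for r in compare_groups(rows)}
        r = res["pro_gain"]
        assert r.effect_size < 0  # subclinical larger => negative

    def test_null_cohort_rarely_bh_significant(self):
        rng = np.random.default_rng(42)
        clean = 0
        for _ in range(40):
            rows = simulate_outcome_rows(26, 26, rng)
            res = compare_groups(rows)
            clean += all(not (r.p_adjusted <= 0.05)
                         for r in res if r.test != "skipped_zero_variance")
        assert clean >= 36

    def test_all_pvalues_valid(self, rng):
        for r in compare_groups(simulate_outcome_rows(26, 26, rng)):
            if r.test == "skipped_zero_variance":
                continue
            assert 0.0 <= r.p_raw <= 1.0
            assert r.p_adjusted >= r.p_raw - 1e-15


class TestAncova:
    def test_hand_computed_small_case(self):
        """n=6 two-group ANCOVA against direct least-squares algebra."""
        y = np.array([3.0, 4.0, 5.0, 6.0, 7.0, 9.0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        cov = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 3.5])
        F, p = ancova_group_effect(y, g, cov)
        # oracle: partial F from nested OLS residual sums of squares
        X_full = np.column_stack([np.ones(6), g == "b", cov])
        X_red = np.column_stack([np.ones(6), cov])
        rss = lambda X: np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        f_oracle = (rss(X_red) - rss(X_full)) / (rss(X_full) / 3)
        p_oracle = sps.f.sf(f_oracle, 1, 3)
        assert F == pytest.approx(f_oracle, abs=1e-9)
        assert p == pytest.approx(p_oracle, abs=1e-9)

    def test_uncorrelated_covariate_leaves_group_p(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(200):
            y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)])
            g = np.array(["a"] * 20 + ["b"] * 20)
            cov = rng.normal(0, 1, 40)
            _, p_adj = ancova_group_effect(y, g, cov)
            p_t = sps.ttest_ind(y[:20], y[20:]).pvalue
            diffs.append(p_adj - p_t)
        assert abs(np.mean(diffs)) < 0.02

    def test_outcome_equal_to_covariate_absorbed(self):
        # outcome IS the covariate: the apparent group difference (the
        # covariate differs by group) vanishes once adjusted
        rng = np.random.default_rng(2)
        g = np.array(["a"] * 20 + ["b"] * 20)
        cov = rng.normal(0, 1, 40) + (g == "b") * 1.5
        y = cov.copy()
        assert sps.ttest_ind(y[:20], y[20:]).pvalue < 0.01
        _, p = ancova_group_effect(y, g, cov)
        assert p > 0.3


class TestPearsonExploratory:
    def test_perfect_linear_relation(self):
        rows = pd.DataFrame({"stai_state": np.arange(10.0),
                             "swj_rate_per_min": 2 * np.arange(10.0) + 1})
        out = pearson_exploratory(rows, ["stai_state"], ["swj_rate_per_min"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_r_threshold_arithmetic(self):
        # r = 0.3 at n = 54 sits just under alpha = 0.05 (p ~ 0.0276)
        x = np.linspace(-1, 1, 54)
        resid = np.sin(np.arange(54) * 2.7)
        resid = resid - np.polyval(np.polyfit(x, resid, 1), x)
        y = 0.3 * x / x.std() + resid * np.sqrt(1 - 0.3 ** 2) / resid.std()
        r, p = sps.pearsonr(x, y)
        t = r * math.sqrt(52 / (1 - r * r))
        assert 2 * sps.t.sf(abs(t), 52) == pytest.approx(p, abs=1e-12)
        assert sps.pearsonr(x, y)[1] == pytest.approx(0.0276, abs=0.002)

    def test_independent_columns_r_distribution(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(200):
            rows = pd.DataFrame({"bmi": rng.normal(22, 2, 54),
                                 "pro_gain": rng.normal(1, 0.05, 54)})
            out = pearson_exploratory(rows, ["bmi"], ["pro_gain"])
            hits += abs(out.loc[0, "r"]) < 0.27  # ~95% band at n=54
        assert hits >= 180

    def test_zero_variance_flagged_missing(self):
        rows = pd.DataFrame({"bmi": [22.0] * 10,
                             "pro_gain": np.arange(10.0)})
        out = pearson_exploratory(rows, ["bmi"], ["pro_gain"])
        assert np.isnan(out.loc[0, "r"])


class TestMahalanobis:
    def test_gross_outlier_flags(self, rng):
        X = np.vstack([rng.normal(0, 1, (60, 2)), [[8.0, 8.0]]])
        _, flags = mahalanobis_outliers(X)
        assert flags[-1]
        assert flags[:-1].sum() <= 1

    def test_matches_direct_formula(self, rng):
        X = rng.normal(0, 1, (55, 7))
        d2, _ = mahalanobis_outliers(X)
        mu = X.mean(axis=0)
        Sinv = np.linalg.inv(np.cov(X, rowvar=False, ddof=1))
        oracle = np.array([(x - mu) @ Sinv @ (x - mu) for x in X])
        assert np.allclose(d2, oracle, atol=1e-9)

    def test_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(0)
        flags = 0
        n_total = 0
        for _ in range(300):
            X = rng.normal(0, 1, (55, 7))
            _, f = mahalanobis_outliers(X, alpha=0.001)
            flags += f.sum()
            n_total += 55
        # expected ~ alpha per observation (sampling inflation allowed)
        assert flags / n_total < 0.01

    def test_singular_covariance_rejected(self):
        X = np.ones((20, 3))
        X[:, 1] = X[:, 0]
        with pytest.raises(ValueError):
            mahalanobis_outliers(X)


class TestLDA:
    def test_perfect_separation(self):
        X = np.vstack([np.random.default_rng(0).normal(0, 0.1, (20, 2)),
                       np.random.default_rng(1).normal(5, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        assert lda_classify(X, y) == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (50, 2))
        y = rng.permutation([0] * 25 + [1] * 25)
        acc = lda_classify(X, y)
        assert 0.2 <= acc <= 0.8

    def test_matches_closed_form_discriminant_small_case(self):
        # 6 points, equal covariance by construction: classify by the
        # sign of w'(x - m) with w = S_pooled^-1 (mu1 - mu0)
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                      [4.0, 4.0], [5.0, 4.0], [4.0, 5.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        acc = lda_classify(X, y)
        correct = 0
        for i in range(6):
            tr = np.delete(np.arange(6), i)
            X0, X1 = X[tr][y[tr] == 0], X[tr][y[tr] == 1]
            S = (np.cov(X0, rowvar=False, ddof=1) * (len(X0) - 1)
                 + np.cov(X1, rowvar=False, ddof=1) * (len(X1) - 1)) / (len(tr) - 2)
            w = np.linalg.solve(S, X1.mean(0) - X0.mean(0))
            thresh = w @ (X0.mean(0) + X1.mean(0)) / 2.0
            pred = int(w @ X[i] > thresh)
            correct += pred == y[i]
        assert acc == pytest.approx(correct / 6.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lda_classify(np.zeros((5, 2)), np.zeros(5))


class TestTTestPower:
    def test_a_priori_sample_size_is_26(self):
        assert required_n_ttest(PowerSpec(d=0.8)) == 26

    def test_returned_n_is_minimal(self):
        n = required_n_ttest(d=0.8, alpha=0.05, power=0.80)
        assert power_twosample_t(n, 0.8) >= 0.80 > power_twosample_t(n - 1, 0.8)

    def test_power_monotone_in_n(self):
        powers = [power_twosample_t(n, 0.8) for n in range(3, 60, 5)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_agrees_with_simulation(self):
        """Noncentral-t power matches Monte-Carlo t-tests at n=26, d=0.8."""
        rng = np.random.default_rng(0)
        reps, n, d = 50_000, 26, 0.8
        a = rng.normal(0.0, 1.0, (reps, n))
        b = rng.normal(d, 1.0, (reps, n))
        p = sps.ttest_ind(a, b, axis=1).pvalue
        mc = np.mean(p < 0.05)
        assert mc == pytest.approx(power_twosample_t(n, d), abs=0.01)

    def test_invalid_effect_rejected(self):
        with pytest.raises(ValueError):
            required_n_ttest(d=-0.1)


class TestPearsonPower:
    def test_reproduces_reported_62_percent(self):
        assert round(100 * power_pearson(0.3, 54, 0.05)) == 62

    def test_null_rho_gives_alpha(self):
        for method in ("nct", "exact", "fisher_z"):
            assert power_pearson(1e-12, 54, 0.05, method=method) == pytest.approx(
                0.05, abs=1e-3)

    def test_exact_method_matches_monte_carlo(self):
        """Exact r-distribution power within 0.01 of simulation."""
        rng = np.random.default_rng(1)
        reps, n, rho = 50_000, 54, 0.3
        X = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=(reps, n))
        xc = X - X.mean(axis=1, keepdims=True)
        r = ((xc[:, :, 0] * xc[:, :, 1]).sum(1)
             / np.sqrt((xc[:, :, 0] ** 2).sum(1) * (xc[:, :, 1] ** 2).sum(1)))
        tcrit = sps.t.ppf(0.975, n - 2)
        rc = tcrit / math.sqrt(n - 2 + tcrit ** 2)
        mc = np.mean(np.abs(r) > rc)
        assert power_pearson(rho, n, 0.05, method="exact") == pytest.approx(mc, abs=0.01)

    def test_exact_density_integrates_to_one(self):
        from scipy import integrate

        from saccadekit.stats import _log_pearson_r_density
        f = lambda x: np.exp(_log_pearson_r_density(x, 0.4, 30))
        total, _ = integrate.quad(f, -1, 1, limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_pearson(1.2, 54)
        with pytest.raises(ValueError):
            power_pearson(0.3, 3)


class TestEffectSizes:
    def test_cohens_d_pooled_sd(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        sp = math.sqrt(((2) * 1.0 + (2) * 1.0) / 4)
        assert cohens_d(a, b) == pytest.approx((2.0 - 3.0) / sp)
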