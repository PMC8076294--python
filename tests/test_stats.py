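"""Statistical battery: exact tests vs brute-force oracles, ICC, regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fundusphere.stats import (
    TestResult,
    UndefinedTestError,
    cohort_report,
    friedman_test,
    holm_adjust,
    icc,
    mann_whitney_u,
    regression_suite,
    wilcoxon_signed_rank,
)


# --------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def brute_friedman_p(x):
    """Exact permutation p by looping over all within-block orderings."""
    ranks = sps.rankdata(x, axis=1)

    def stat(r):
        n, k = r.shape
        col = r.sum(axis=0)
        chi = 12.0 / (n * k * (k + 1)) * sum((c - n * (k + 1) / 2) ** 2 for c in col)
        ties = sum(
            sum(c**3 - c for c in np.unique(row, return_counts=True)[1]) for row in r
        )
        corr = 1.0 - ties / (n * k * (k * k - 1))
        return 0.0 if corr <= 0 else chi / corr

    obs = stat(ranks)
    hits = total = 0
    for combo in itertools.product(*[list(itertools.permutations(row)) for row in ranks]):
        total += 1
        if stat(np.array(combo)) >= obs - 1e-12:
            hits += 1
    return hits / total


def brute_wilcoxon_p(d):
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    tot = ranks.sum()
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    hits = 0
    for signs in itertools.product([1, -1], repeat=len(d)):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        if min(wp, tot - wp) <= w_obs + 1e-12:
            hits += 1
    return hits / 2 ** len(d)


def brute_mannwhitney_p(x, y):
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


# --------------------------------------------------------------------------


class TestFriedman:
    def test_identically_ranked_blocks_statistic(self):
        # 3 blocks, k = 3, same ordering everywhere: chi2 = 6 by the rank formula
        r = friedman_test(np.array([[1.0, 5.0, 9.0]] * 3))
        assert r.statistic == pytest.approx(6.0)

    def test_identical_columns_gives_zero(self):
        r = friedman_test(np.ones((4, 3)) * np.arange(4)[:, None])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_asymptotic_statistic_matches_scipy(self, rng):
        x = rng.normal(size=(12, 4))
        ours = friedman_test(x)
        ref = sps.friedmanchisquare(*x.T)
        assert ours.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 3))
        assert friedman_test(x, exact=True).p_value == pytest.approx(brute_friedman_p(x))

    def test_exact_p_with_ties_equals_enumeration(self):
        x = np.array([[1.0, 1.0, 2.0], [3.0, 1.0, 2.0], [2.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        assert friedman_test(x, exact=True).p_value == pytest.approx(brute_friedman_p(x))

    def test_missing_cells_rejected(self):
        x = np.array([[1.0, np.nan, 2.0], [3.0, 1.0, 2.0]])
        with pytest.raises(ValueError):
            friedman_test(x)


class TestWilcoxon:
    def test_hand_ranked_statistic(self):
        # |d| = (1,2,3,4) -> ranks (1,2,3,4); W- carries the rank of -4
        r = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, -4.0]))
        assert r.statistic == 4.0

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank(np.array([1.0, 2.0]), np.array([1.0, 2.0]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_equals_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.4, 1.0, 6)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(brute_wilcoxon_p(d))

    def test_exact_p_with_ties_equals_enumeration(self):
        d = np.array([1.0, -1.0, 2.0, 2.0, -3.0, 0.5])
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(brute_wilcoxon_p(d))

    def test_exact_matches_scipy_without_ties(self, rng):
        d = rng.normal(0.5, 1.0, 12)
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            sps.wilcoxon(d, method="exact").pvalue
        )

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, 60)
        r = wilcoxon_signed_rank(d)
        assert r.method == "wilcoxon_normal"
        assert 0.0 <= r.p_value <= 1.0


class TestMannWhitney:
    def test_extreme_arrangement(self):
        # x entirely below y: U = 0; 2 of C(4,2)=6 arrangements are as extreme
        r = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1.0 / 3.0)

    def test_identical_samples_p_one(self):
        assert mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_equals_arrangement_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(0.8, 1.0, 5)
        assert mann_whitney_u(x, y).p_value == pytest.approx(brute_mannwhitney_p(x, y))

    def test_exact_p_with_ties_equals_enumeration(self):
        x, y = np.array([1.0, 2.0, 2.0, 5.0]), np.array([2.0, 3.0, 4.0])
        assert mann_whitney_u(x, y).p_value == pytest.approx(brute_mannwhitney_p(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_stepdown(self):
        # sorted: .01*3=.03; .03*2=.06; .04*1=.04 -> monotone .06
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_dominates_input_and_matches_bonferroni_for_smallest(self, rng):
        p = rng.uniform(size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert adj[np.argmin(p)] == pytest.approx(min(1.0, p.min() * len(p)))

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=6)
        perm = rng.permutation(6)
        assert np.allclose(holm_adjust(p)[perm], holm_adjust(p[perm]))


class TestICC:
    def test_perfect_agreement(self, rng):
        a = rng.normal(size=8)
        assert icc(np.stack([a, a], axis=1)) == pytest.approx(1.0)

    def test_mean_squares_hand_oracle(self):
        """6 x 2 table: ICC(2,1) from explicitly computed ANOVA mean squares."""
        x = np.array([[9.0, 10.0], [6.0, 7.0], [8.0, 8.0], [7.0, 9.0], [10.0, 12.0], [6.0, 5.0]])
        n, k = x.shape
        grand = x.mean()
        msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum() / (
            (n - 1) * (k - 1)
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(x, model="ICC2") == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        subj = rng.normal(0, 2, 10)
        x = np.stack([subj + rng.normal(0, 0.5, 10), subj + 0.3 + rng.normal(0, 0.5, 10)], axis=1)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(10), 2),
                "rater": np.tile([0, 1], 10),
                "score": x.reshape(-1),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])  # label changed across versions
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(x, model="ICC2") == pytest.approx(icc2, rel=1e-9)

    def test_shuffled_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            a = rng.normal(size=12)
            vals.append(icc(np.stack([a, rng.permutation(a)], axis=1)))
        assert abs(np.mean(vals)) < 0.15

    def test_degenerate_table_flagged(self):
        with pytest.warns(RuntimeWarning):
            out = icc(np.ones((6, 2)))
        assert np.isnan(out)


class TestRegression:
    def _table(self, rng, n=74, beta_al=0.0, beta_sex=0.0, noise=1.0):
        sex = rng.choice(["M", "F"], n)
        al = rng.normal(24.92, 1.11, n)
        age = rng.normal(36.5, 10.0, n)
        es = rng.normal(-3.3, 2.6, n)
        y = beta_al * al + beta_sex * (sex == "M") + rng.normal(0, noise, n)
        return pd.DataFrame(
            {"eye_id": range(n), "resp": y, "age_yr": age, "sex": sex, "es_diopters": es, "axial_length_mm": al}
        )

    def test_strong_al_signal_always_selected(self):
        """AL drives the response: both criteria keep it; the stricter p-value
        rule selects it exclusively in most replicates (AIC admits a spurious
        term with prob ~ P(chi2_1 > 2) ~ 0.16 per noise variable by design)."""
        aic_has_al = pval_exact = 0
        for seed in range(20):
            t = self._table(np.random.default_rng(seed), beta_al=1.0, noise=0.1)
            aic_has_al += "axial_length_mm" in regression_suite(t, "resp").selected
            pval_exact += regression_suite(t, "resp", criterion="pvalue").selected == [
                "axial_length_mm"
            ]
        assert aic_has_al == 20
        assert pval_exact >= 12  # expected ~ 0.95^3 of replicates

    def test_pure_noise_rarely_selects(self):
        """No signal anywhere: the p-value rule usually returns the empty model
        and AIC keeps at most an occasional spurious term."""
        pval_empty = aic_sizes = 0
        for seed in range(20):
            t = self._table(np.random.default_rng(100 + seed), noise=1.0)
            pval_empty += len(regression_suite(t, "resp", criterion="pvalue").selected) == 0
            aic_sizes += len(regression_suite(t, "resp").selected)
        assert pval_empty >= 11  # expected ~ 0.95^4 of replicates
        assert aic_sizes / 20 < 1.5  # AIC spurious-retention rate ~ 0.16/variable

    def test_perfect_single_predictor(self, rng):
        t = self._table(rng, beta_al=2.0, noise=1e-9)
        rep = regression_suite(t, "resp", predictors=("axial_length_mm",))
        fit = rep.simple["axial_length_mm"]
        assert fit.pearson_r == pytest.approx(1.0, abs=1e-6)
        assert fit.p_value < 1e-12

    def test_collinear_predictors_named(self, rng):
        t = self._table(rng)
        t["al_copy"] = t["axial_length_mm"]
        with pytest.raises(ValueError, match="collinear"):
            regression_suite(t, "resp", predictors=("axial_length_mm", "al_copy"))

    def test_pvalue_criterion_variant(self, rng):
        t = self._table(rng, beta_al=1.0, noise=0.1)
        rep = regression_suite(t, "resp", criterion="pvalue")
        assert "axial_length_mm" in rep.selected


class TestCohortReport:
    def test_report_covers_battery(self):
        from fundusphere.phantom import PhantomConfig, generate_cohort
        from fundusphere.pipeline import measure_cohort_truth

        truth = generate_cohort(PhantomConfig(n_eyes=40, seed=9))
        _, cohort = measure_cohort_truth(truth)
        rep = cohort_report(cohort)
        assert isinstance(rep["friedman_distances"], TestResult)
        assert len(rep["pairwise_distances"]) == 6
        for t in rep["pairwise_distances"].values():
            assert t.adjusted_p >= t.p_value - 1e-12
        assert "counts_by_sex" in rep
        assert "regression_counts" in rep
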