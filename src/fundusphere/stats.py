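"""Nonparametric statistics for per-eye ampulla measurement tables.

The battery matches how normative ophthalmic cohorts of this kind are
analyzed: Friedman tests across the four matched sectors, Wilcoxon
signed-rank tests for paired sector contrasts, Mann–Whitney U tests for
sex differences, Holm correction over families of tests, intraclass
correlation coefficients for rater/occasion repeatability, and simple plus
stepwise multiple linear regression of counts and distances on demographics.

Exact small-sample p-values are computed by full enumeration (Friedman),
rank-sum convolution over sign assignments (Wilcoxon), and enumeration of
group assignments (Mann–Whitney); ties are mid-ranked throughout and exact
paths handle them correctly.  Asymptotic paths use the usual tie-corrected
normal / chi-square approximations.  All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UndefinedTestError",
    "TestResult",
    "friedman_test",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "holm_adjust",
    "icc",
    "SimpleFit",
    "RegressionReport",
    "regression_suite",
    "cohort_report",
]


class UndefinedTestError(ValueError):
    """The test statistic is undefined for this input (e.g. all-zero diffs)."""


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    adjusted_p: float | None = None


# ---------------------------------------------------------------------------
# Friedman test


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from per-block mid-ranks (n, k)."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    chi = 12.0 / (n * k * (k + 1)) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    ties = 0.0
    for row in ranks:
        _, cnt = np.unique(row, return_counts=True)
        ties += np.sum(cnt**3 - cnt)
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0.0:
        # every block fully tied: no evidence either way
        return 0.0
    return float(chi / correction)


def friedman_test(blocks, exact: bool = False, max_enumeration: int = 2_000_000) -> TestResult:
    """Friedman rank test across k matched conditions (rows = blocks/eyes).

    Parameters
    ----------
    blocks:
        Array-like of shape ``(n, k)``; no missing cells (listwise deletion
        is the caller's job).
    exact:
        Enumerate all ``(k!)^n`` within-block orderings for an exact
        permutation p-value (guarded by ``max_enumeration``); otherwise the
        asymptotic chi-square with ``k - 1`` df is used.
    """
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (n >= 2) x (k >= 2) table of matched values")
    if np.isnan(x).any():
        raise ValueError("missing cells; drop incomplete blocks before testing")
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    stat = _friedman_statistic(ranks)

    if exact:
        total = math.factorial(k) ** n
        if total > max_enumeration:
            raise ValueError(
                f"exact Friedman enumeration needs {total} orderings (> {max_enumeration})"
            )
        perms_per_row = [
            [np.asarray(p) for p in itertools.permutations(row)] for row in ranks
        ]
        count = 0
        for combo in itertools.product(*perms_per_row):
            if _friedman_statistic(np.vstack(combo)) >= stat - 1e-12:
                count += 1
        p = count / total
        method = "friedman_exact"
    else:
        p = float(sps.chi2.sf(stat, k - 1))
        method = "friedman_chi2"
    return TestResult(statistic=stat, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of 2*W+ over sign assignments (counts array)."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist


def wilcoxon_signed_rank(x, y=None, exact_below_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (the classic Wilcoxon policy); ties among
    the absolute differences are mid-ranked.  The statistic is
    ``W = min(W+, W-)``.  For ``n <= exact_below_n`` the p-value is exact —
    the distribution of the rank sum over all ``2^n`` sign assignments,
    computed by convolution and valid under ties — otherwise a tie-corrected
    normal approximation with continuity correction is used.

    Raises
    ------
    UndefinedTestError
        If every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    w = min(w_plus, total - w_plus)

    if n <= exact_below_n:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        dist = _signed_rank_distribution(ranks2)
        denom = dist.sum()
        w2 = int(round(2.0 * w))
        lo = dist[: w2 + 1].sum()
        hi = dist[int(round(2.0 * total)) - w2 :].sum()
        overlap = 0.0
        if w2 >= int(round(2.0 * total)) - w2:  # the two tails meet
            overlap = dist[int(round(2.0 * total)) - w2 : w2 + 1].sum()
        p = min(1.0, (lo + hi - overlap) / denom)
        method = "wilcoxon_exact"
    else:
        mean = n * (n + 1) / 4.0
        _, cnt = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(cnt**3 - cnt) / 48.0
        z = (w - mean + 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
        method = "wilcoxon_normal"
    return TestResult(statistic=w, p_value=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Mann-Whitney U test


def mann_whitney_u(x, y, exact_max_enumeration: int = 400_000) -> TestResult:
    """Two-sided Mann–Whitney U test for two independent samples.

    The reported statistic is ``U`` of the first sample.  When
    ``min(n1, n2) <= 10`` and the enumeration is affordable, the p-value is
    exact: all ``C(n1 + n2, n1)`` assignments of the pooled mid-ranks are
    enumerated and the two-sided p is the fraction of assignments at least as
    far from the null mean ``n1 n2 / 2`` as the observed U (correct under
    ties).  Otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    n_comb = math.comb(n1 + n2, n1)
    if min(n1, n2) <= 10 and n_comb <= exact_max_enumeration:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n1 + n2), n1)),
            dtype=int,
            count=n_comb * n1,
        ).reshape(n_comb, n1)
        u_all = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= abs(u1 - mu) - 1e-12))
        method = "mannwhitney_exact"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "mannwhitney_normal"
    return TestResult(statistic=u1, p_value=p, n=n1 + n2, method=method)


# ---------------------------------------------------------------------------
# Multiplicity and agreement


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def icc(ratings, model: str = "ICC2", average: bool = False) -> float:
    """Intraclass correlation coefficient from a subjects x raters table.

    Parameters
    ----------
    ratings:
        Complete two-way table, shape ``(n_subjects >= 5, k_raters >= 2)``.
    model:
        ``"ICC1"`` (one-way random), ``"ICC2"`` (two-way random, absolute
        agreement — the default, appropriate for occasion/rater
        repeatability), or ``"ICC3"`` (two-way mixed, consistency).
    average:
        Return the average-measure form (ICCx,k) instead of single-measure.

    Returns NaN (with a warning) when the coefficient is undefined because
    there is no between-subject variance.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need a complete table of >= 5 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("ICC requires a complete table")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_cols + ss_err) / (n * (k - 1))  # one-way within-subject MS

    if model == "ICC1":
        denom = msr + (k - 1) * msw if not average else msr
        num = msr - msw if not average else msr - msw
    elif model == "ICC2":
        if average:
            denom = msr + (msc - mse) / n
        else:
            denom = msr + (k - 1) * mse + k * (msc - mse) / n
        num = msr - mse
    elif model == "ICC3":
        denom = msr + (k - 1) * mse if not average else msr
        num = msr - mse
    else:
        raise ValueError("model must be 'ICC1', 'ICC2' or 'ICC3'")
    if denom <= 0.0 or (msr <= 0.0 and model != "ICC1"):
        warnings.warn("no between-subject variance; ICC undefined", RuntimeWarning)
        return float("nan")
    return float(num / denom)


# ---------------------------------------------------------------------------
# Regression


@dataclass
class SimpleFit:
    predictor: str
    coef: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass
class RegressionReport:
    response: str
    simple: dict[str, SimpleFit]
    selected: list[str]
    multiple_params: dict[str, float]
    multiple_pvalues: dict[str, float]
    multiple_r2: float
    criterion: str


def _fit_ols(df: pd.DataFrame, response: str, predictors: list[str]):
    exog = sm.add_constant(df[predictors], has_constant="add") if predictors else pd.DataFrame(
        {"const": np.ones(len(df))}, index=df.index
    )
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        corr = df[predictors].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(predictors) > 1 else (predictors[0],)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {worst}")
    return sm.OLS(df[response], exog).fit()


def _encode(table: pd.DataFrame, predictors) -> pd.DataFrame:
    df = table.copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "M").astype(float)
    return df


def regression_suite(
    table: pd.DataFrame,
    response: str,
    predictors=("age_yr", "sex", "es_diopters", "axial_length_mm"),
    criterion: str = "aic",
    enter_p: float = 0.05,
    remove_p: float = 0.10,
) -> RegressionReport:
    """Per-predictor simple OLS fits plus a bidirectional stepwise multiple fit.

    Each predictor first gets its own simple regression (slope, Pearson or
    point-biserial correlation, p-value).  Then bidirectional stepwise
    selection — by AIC starting from the full model (default), or by
    p-value thresholds (``criterion="pvalue"``, enter/remove 0.05/0.10)
    starting from the empty model — picks the multiple model, which is refit
    and reported.
    """
    predictors = [p for p in predictors if p in table.columns]
    df = _encode(table, predictors).dropna(subset=[response, *predictors])
    if len(df) < 10:
        raise ValueError("need at least 10 complete rows for the regression suite")

    simple: dict[str, SimpleFit] = {}
    for p in predictors:
        fit = _fit_ols(df, response, [p])
        r, _ = sps.pearsonr(df[p], df[response])
        simple[p] = SimpleFit(
            predictor=p,
            coef=float(fit.params[p]),
            intercept=float(fit.params["const"]),
            pearson_r=float(r),
            p_value=float(fit.pvalues[p]),
            n=len(df),
        )

    if criterion == "aic":
        current = list(predictors)
        best_aic = _fit_ols(df, response, current).aic
        improved = True
        while improved:
            improved = False
            moves = [("drop", p) for p in current] + [
                ("add", p) for p in predictors if p not in current
            ]
            for action, p in moves:
                cand = [q for q in current if q != p] if action == "drop" else current + [p]
                aic = _fit_ols(df, response, cand).aic
                if aic < best_aic - 1e-9:
                    best_aic, current, improved = aic, cand, True
        selected = current
    elif criterion == "pvalue":
        selected = []
        while True:
            remaining = [p for p in predictors if p not in selected]
            entry = None
            best_p = enter_p
            for p in remaining:
                fit = _fit_ols(df, response, selected + [p])
                if fit.pvalues[p] < best_p:
                    best_p, entry = fit.pvalues[p], p
            if entry is not None:
                selected.append(entry)
            if selected:
                fit = _fit_ols(df, response, selected)
                worst = max(selected, key=lambda q: fit.pvalues[q])
                if fit.pvalues[worst] > remove_p:
                    selected.remove(worst)
                    continue
            if entry is None:
                break
    else:
        raise ValueError("criterion must be 'aic' or 'pvalue'")

    final = _fit_ols(df, response, selected)
    return RegressionReport(
        response=response,
        simple=simple,
        selected=selected,
        multiple_params={k: float(v) for k, v in final.params.items()},
        multiple_pvalues={k: float(v) for k, v in final.pvalues.items()},
        multiple_r2=float(final.rsquared) if selected else 0.0,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# Cohort-level report


def cohort_report(cohort: pd.DataFrame) -> dict:
    """The full battery over a per-eye cohort table.

    Expects the column layout produced by
    :func:`fundusphere.measurement.cohort_table`: ``n_UL..n_LN``,
    ``dist_UL..dist_LN``, ``n_total``, ``mean_distance_mm`` and covariates.
    Eyes with an empty sector are dropped listwise from the matched-sector
    tests.  Pairwise sector contrasts are Holm-adjusted within each family.
    """
    from .localization import SECTORS  # local import to avoid cycle at import time

    report: dict = {}
    counts = cohort[[f"n_{s}" for s in SECTORS]].to_numpy(dtype=float)
    report["friedman_counts"] = friedman_test(counts)

    dists = cohort[[f"dist_{s}" for s in SECTORS]].dropna()
    report["friedman_distances"] = friedman_test(dists.to_numpy())

    pairs = list(itertools.combinations(SECTORS, 2))
    raw = []
    for a, b in pairs:
        raw.append(wilcoxon_signed_rank(dists[f"dist_{a}"], dists[f"dist_{b}"]))
    adj = holm_adjust([t.p_value for t in raw])
    for t, ap in zip(raw, adj):
        t.adjusted_p = float(ap)
    report["pairwise_distances"] = dict(zip([f"{a}_vs_{b}" for a, b in pairs], raw))

    if "sex" in cohort.columns:
        men = cohort[cohort["sex"] == "M"]
        women = cohort[cohort["sex"] == "F"]
        if len(men) and len(women):
            report["counts_by_sex"] = mann_whitney_u(men["n_total"], women["n_total"])

    preds = [p for p in ("age_yr", "sex", "es_diopters", "axial_length_mm") if p in cohort.columns]
    if len(preds) >= 2 and len(cohort) >= 10:
        report["regression_counts"] = regression_suite(cohort, "n_total", preds)
        report["regression_distances"] = regression_suite(cohort, "mean_distance_mm", preds)
    return report
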