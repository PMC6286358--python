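"""The cohort statistical battery.

Rank-based correlations (Spearman, first-order partial Spearman), ordinary
multiple regression of an attribute on age and education, Kruskal-Wallis
with Wilcoxon rank-sum post hocs under Bonferroni correction, distributional
checks (Kolmogorov-Smirnov normality screen, Levene homogeneity of
variance), and a 2x2 chi-square for dropout proportions. All functions are
pure: identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "StatResult",
    "RegressionResult",
    "CorrectedAlpha",
    "spearman",
    "partial_spearman",
    "multiple_regression",
    "group_tests",
    "distribution_checks",
    "proportion_test",
    "bonferroni",
]


@dataclass
class StatResult:
    """One test or correlation outcome with its correction context."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    alpha_corrected: float | None = None
    significant: bool | None = None
    covariates: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.alpha_corrected is not None and self.significant is None:
            self.significant = bool(self.p_value < self.alpha_corrected)


class CorrectedAlpha(NamedTuple):
    """Bonferroni-corrected level: exact value plus 4-decimal report form."""

    exact: float
    reported: float


def bonferroni(alpha: float, m: int) -> CorrectedAlpha:
    """Bonferroni-corrected significance level alpha/m.

    The exact quotient is used for decisions; the value rounded to four
    decimals is what tables print (0.05/8 -> 0.0063).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    exact = alpha / m
    return CorrectedAlpha(exact=exact, reported=round(exact, 4))


def _as_arrays(*vecs) -> list[np.ndarray]:
    arrs = [np.asarray(v, dtype=float) for v in vecs]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("input vectors must have equal length")
    return arrs


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    alpha_corrected: float | None = None,
    exact: bool = False,
    n_perm: int = 10000,
    seed: int = 0,
) -> StatResult:
    """Spearman rank correlation with midrank ties, two-sided p.

    The p-value uses the t approximation (standard at cohort sample sizes);
    ``exact=True`` switches to a permutation p-value with ``n_perm`` draws.
    """
    x, y = _as_arrays(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho undefined for a constant vector")
    if exact:
        rng = np.random.default_rng(seed)
        res = sps.permutation_test(
            (x,), lambda xs: sps.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=n_perm,
            alternative="two-sided", rng=rng)
        rho, p = float(sps.spearmanr(x, y).statistic), float(res.pvalue)
    else:
        r = sps.spearmanr(x, y)
        rho, p = float(r.statistic), float(r.pvalue)
    return StatResult("spearman", rho, p, int(x.size),
                      alpha_corrected=alpha_corrected)


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    alpha_corrected: float | None = None,
    covariate_name: str = "z",
) -> StatResult:
    """First-order partial Spearman correlation of x and y given z.

    All three vectors are midrank-transformed, the Pearson correlations of
    the ranks are combined as

        r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

    and the p-value comes from a t statistic on n - 3 degrees of freedom.
    """
    x, y, z = _as_arrays(x, y, z)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(z) == 0:
        # constant covariate adjusts nothing
        plain = spearman(x, y, alpha_corrected=alpha_corrected)
        plain.test_name = "partial_spearman"
        plain.covariates = [covariate_name]
        plain.note = "constant covariate; equals plain Spearman"
        return plain
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    det = (1 - r_xz**2) * (1 - r_yz**2)
    if det <= 1e-12:
        raise ValueError("partial correlation undefined: covariate collinear "
                         "with x or y in ranks")
    r = (r_xy - r_xz * r_yz) / np.sqrt(det)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(tstat), df))
    return StatResult("partial_spearman", r, p, n,
                      alpha_corrected=alpha_corrected,
                      covariates=[covariate_name])


@dataclass
class RegressionResult:
    """attribute ~ intercept + age + education, ordinary least squares."""

    r_squared: float
    p_overall: float
    coef_age: float
    coef_edu: float
    coef_diff: float  # coef_edu - coef_age
    n: int

    def __post_init__(self) -> None:
        assert np.isclose(self.coef_diff, self.coef_edu - self.coef_age)


def multiple_regression(
    attribute: Sequence[float],
    age: Sequence[float],
    education: Sequence[float],
) -> RegressionResult:
    """OLS of an attribute on age and education jointly.

    Reports R^2, the overall F-test p-value, both slopes, and their
    difference (education minus age), the study's summary of which time
    variable dominates.
    """
    y, a, e = _as_arrays(attribute, age, education)
    if y.size < 4:
        raise ValueError("need at least 4 observations")
    X = sm.add_constant(np.column_stack([a, e]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: age and education collinear")
    fit = sm.OLS(y, X).fit()
    coef_age, coef_edu = float(fit.params[1]), float(fit.params[2])
    return RegressionResult(
        r_squared=float(fit.rsquared),
        p_overall=float(fit.f_pvalue),
        coef_age=coef_age,
        coef_edu=coef_edu,
        coef_diff=coef_edu - coef_age,
        n=int(y.size),
    )


def _rank_sum_W(a: np.ndarray, b: np.ndarray) -> float:
    """Wilcoxon rank-sum statistic: sum of ranks of the first sample."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum())


def group_tests(
    values_by_group: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]] | None = None,
    m_corrections: int | None = None,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Kruskal-Wallis across groups, then pairwise Wilcoxon rank-sum post hocs.

    Pairwise tests are two-tailed; the exact rank-sum distribution is used
    when both groups have at most 10 observations and no ties span them,
    otherwise the normal approximation with tie and continuity corrections.
    Each post hoc carries the Bonferroni-corrected level alpha/m (m
    defaults to the number of comparisons).
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 observations")
    if comparisons is None:
        names = list(groups)
        comparisons = [(names[i], names[j]) for i in range(len(names))
                       for j in range(i + 1, len(names))]
    m = m_corrections if m_corrections is not None else max(len(comparisons), 1)
    alpha_c = bonferroni(alpha, m).exact

    kw = sps.kruskal(*groups.values())
    results = [StatResult("kruskal_wallis", float(kw.statistic),
                          float(kw.pvalue),
                          int(sum(v.size for v in groups.values())))]
    for g1, g2 in comparisons:
        a, b = groups[g1], groups[g2]
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (a.size <= 10 and b.size <= 10 and no_ties) \
            else "asymptotic"
        mw = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=True)
        results.append(StatResult(
            f"wilcoxon_ranksum[{g1} vs {g2}]",
            _rank_sum_W(a, b),
            float(mw.pvalue),
            int(a.size + b.size),
            alpha_corrected=alpha_c,
        ))
    return results


def distribution_checks(
    values_by_group: Mapping[str, Sequence[float]],
    center: str = "mean",
) -> list[StatResult]:
    """Normality screen (KS) per group plus Levene variance homogeneity.

    The one-sample Kolmogorov-Smirnov test compares each group with a
    normal distribution at the group's own estimated mean and sd — an
    approximate screen (estimating the moments inflates the p-value), used
    to motivate nonparametric group tests rather than as a calibrated test.
    Levene's test defaults to the mean center (classic form); pass
    ``center="median"`` for the Brown-Forsythe variant.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    results = []
    for g, v in groups.items():
        if v.size < 4:
            raise ValueError(f"group {g!r} needs >= 4 observations")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} is constant; KS degenerate")
        ks = sps.kstest(v, "norm", args=(v.mean(), sd))
        results.append(StatResult(
            f"ks_normality[{g}]", float(ks.statistic), float(ks.pvalue),
            int(v.size), note="approximate: normal parameters estimated "
            "from the same sample"))
    if len(groups) >= 2:
        lev = sps.levene(*groups.values(), center=center)
        results.append(StatResult(
            f"levene[{center}]", float(lev.statistic), float(lev.pvalue),
            int(sum(v.size for v in groups.values()))))
    return results


def proportion_test(
    k1: int, n1: int, k2: int, n2: int,
    continuity: bool = False,
) -> StatResult:
    """2x2 chi-square comparison of two proportions (k1/n1 vs k2/n2).

    No continuity correction by default; ``continuity=True`` applies Yates.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if k1 / n1 == k2 / n2:
        # expected == observed; chi2_contingency would also return 0/1 but
        # the degenerate all-zero margin case needs guarding
        return StatResult("chi_square_2x2", 0.0, 1.0, n1 + n2)
    chi2 = sps.chi2_contingency(table, correction=continuity)
    return StatResult("chi_square_2x2", float(chi2.statistic),
                      float(chi2.pvalue), n1 + n2)
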