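"""Association statistics used throughout the pipeline.

Pearson chi-square (uncorrected, with an optional fixed-margin resampled
null), Fisher's exact test with the conditional-MLE odds ratio and exact
CI, a K-sample permutation test built on the one-way ANOVA F statistic,
TukeyHSD pairwise comparisons with Benjamini-Hochberg adjustment, and
ordinary least-squares regression.

The chi-square statistic deliberately carries no continuity correction:
dichotomized-marker association tables in this analysis are evaluated with
the plain Pearson statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.sandbox.stats.multicomp import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class StatsError(ValueError):
    pass


@dataclass
class ContingencyResult:
    table: np.ndarray
    chi2: float
    df: int
    p_asymptotic: float
    p_resampled: Optional[float] = None
    n_resamples: int = 0
    seed: Optional[int] = None


@dataclass
class FisherResult:
    table: np.ndarray
    or_cmle: float  # may be 0 or +inf for tables with empty cells
    ci_low: float
    ci_high: float
    p: float


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r: float
    p_slope: float
    n: int


@dataclass
class PermTestResult:
    statistic: float
    p: float
    method: str  # asymptotic | monte_carlo
    n_perm: int = 0
    seed: Optional[int] = None


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    p_raw: float
    p_adjusted: float


def _validate_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise StatsError("table must be 2-dimensional")
    if np.any(t < 0):
        raise StatsError("negative counts")
    if not np.allclose(t, np.round(t)):
        raise StatsError("counts must be integers")
    return t.astype(int)


def pearson_chi_square(table) -> ContingencyResult:
    """Uncorrected Pearson chi-square with asymptotic p."""
    t = _validate_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise StatsError("zero row/column margin")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(table=t, chi2=float(chi2), df=int(df), p_asymptotic=float(p))


def resampled_p(table, n_resamples: int = 10000, seed: int = 0) -> ContingencyResult:
    """Monte-Carlo chi-square p from tables resampled with fixed margins.

    p = (1 + #{resampled chi2 >= observed}) / (n_resamples + 1); never 0.
    """
    if n_resamples < 100:
        raise StatsError("n_resamples must be >= 100")
    res = pearson_chi_square(table)
    t = res.table
    rng = np.random.default_rng(seed)
    row, col = t.sum(axis=1), t.sum(axis=0)
    E = np.outer(row, col) / t.sum()
    draws = sps.random_table(row, col).rvs(n_resamples, random_state=rng)
    chi2s = ((draws - E) ** 2 / E).sum(axis=(1, 2))
    exceed = int(np.sum(chi2s >= res.chi2 - 1e-12))
    res.p_resampled = (1 + exceed) / (n_resamples + 1)
    res.n_resamples = n_resamples
    res.seed = seed
    return res


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio and
    exact 95% CI.  Tables with an empty cell yield OR 0 or +inf with one
    finite CI bound."""
    t = _validate_table(table)
    if t.shape != (2, 2):
        raise StatsError("fisher_exact_2x2 requires a 2x2 table")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    orr = _odds_ratio(t, kind="conditional")
    ci = orr.confidence_interval(confidence_level=0.95)
    return FisherResult(
        table=t,
        or_cmle=float(orr.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p=float(p),
    )


def fisher_p_oracle(table) -> float:
    """Independent two-sided Fisher p by hypergeometric enumeration over
    all tables with the observed margins (test oracle)."""
    t = _validate_table(table)
    r1, r2 = t.sum(axis=1)
    c1 = t[:, 0].sum()
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    probs = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = sps.hypergeom.pmf(t[0, 0], n, r1, c1)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


def ksample_permutation_test(
    values,
    groups,
    mode: str = "asymptotic",
    n_perm: int = 9999,
    seed: int = 0,
) -> PermTestResult:
    """K-sample location test on the one-way ANOVA F statistic.

    ``asymptotic`` uses the F reference distribution; ``monte_carlo``
    permutes group labels.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise StatsError("need >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if mode == "asymptotic" and any(len(s) < 2 for s in samples):
        raise StatsError("asymptotic mode needs >= 2 members per group")

    def f_stat(parts):
        with np.errstate(invalid="ignore", divide="ignore"):
            f, _ = sps.f_oneway(*parts)
        return 0.0 if not np.isfinite(f) else float(f)

    f = f_stat(samples)
    n = len(values)
    k = len(labels)
    if mode == "asymptotic":
        p = float(sps.f.sf(f, k - 1, n - k)) if f > 0 else 1.0
        return PermTestResult(statistic=f, p=p, method="asymptotic")
    if mode != "monte_carlo":
        raise StatsError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    sizes = [len(s) for s in samples]
    cuts = np.cumsum(sizes)[:-1]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        if f_stat(np.split(perm, cuts)) >= f - 1e-12:
            exceed += 1
    return PermTestResult(
        statistic=f, p=(1 + exceed) / (n_perm + 1), method="monte_carlo",
        n_perm=n_perm, seed=seed,
    )


def pairwise_tukey_bh(values, groups) -> list[PairwiseComparison]:
    """TukeyHSD pairwise comparisons, then Benjamini-Hochberg adjustment
    across the comparison list (the procedure applied to expression
    differences across CNA states)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 3:
        raise StatsError("need >= 3 groups for pairwise comparisons")
    if any(np.sum(groups == g) < 2 for g in labels):
        raise StatsError("every group needs >= 2 members")
    res = pairwise_tukeyhsd(values, groups)
    raw = np.asarray(res.pvalues, dtype=float)
    adjusted = multipletests(raw, method="fdr_bh")[1]
    uniq = list(res.groupsunique)
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    return [
        PairwiseComparison(str(a), str(b), float(diff), float(p_raw), float(p_adj))
        for (a, b), diff, p_raw, p_adj in zip(pairs, res.meandiffs, raw, adjusted)
    ]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def ols_regression(x, y) -> RegressionFit:
    """Least-squares line of y on x with a two-sided t test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need matched x, y with n >= 3")
    if np.ptp(x) == 0:
        raise StatsError("constant x")
    fit = sps.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), p_slope=float(fit.pvalue), n=len(x),
    )
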