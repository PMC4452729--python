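"""Group-level inference for the 2x3 factorial design.

Factorial ANOVA (Type III, sum-to-zero coding, so the unbalanced n=17
cell is handled), Bonferroni-corrected two-sample post-hoc comparisons
with an automatic Welch correction triggered by a variance F-test,
unconditional (Barnard) and conditional (Fisher) exact tests for the rare
binary perseveration outcome, and Spearman rank correlations for
behavior-protein associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

WELCH_TRIGGER_ALPHA = 0.05  # variance-test p below this switches the t-test to Welch


@dataclass(frozen=True)
class PairwiseResult:
    """One two-sample comparison (possibly Bonferroni adjusted)."""

    group_a: str
    group_b: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float | None = None
    correction: str | None = None
    welch_applied: bool = False
    mean_difference: float = np.nan


@dataclass(frozen=True)
class ExactTestResult:
    """Exact test on a 2x2 table (rows = groups, cols = event / no event)."""

    table: tuple[tuple[int, int], tuple[int, int]]
    method: str
    p_two_sided: float
    statistic: float = np.nan  # Barnard's Wald score T; undefined for Fisher
    pi_sup: float = np.nan     # nuisance success rate attaining the supremum


@dataclass(frozen=True)
class VarianceTestResult:
    """Two-sided F-test for equality of two variances."""

    F: float
    df1: int
    df2: int
    p_two_sided: float


def _as_clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


# ---------------------------------------------------------------------------
# factorial ANOVA


def _sum_code(labels: np.ndarray, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) coding: L levels -> L-1 columns."""
    n = len(labels)
    cols = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[:, j] = (labels == lev).astype(float)
    cols[labels == levels[-1], :] = -1.0
    return cols


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Two-factor ANOVA with Type III sums of squares.

    Factors are sum-to-zero coded and each term's SS is the increase in
    residual SS when the term's columns are dropped from the full
    (interaction) model — the model-comparison definition of Type III,
    valid for mildly unbalanced designs. Returns a table indexed by
    ``factor_a``, ``factor_b``, ``interaction``, ``residual`` with columns
    ``sum_sq, df, F, p``.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    ok = np.isfinite(y)
    y, a, b = y[ok], a[ok], b[ok]
    lev_a = sorted(pd.unique(a))
    lev_b = sorted(pd.unique(b))
    if len(lev_a) < 2 or len(lev_b) < 2:
        raise ValueError("both factors need at least 2 levels")
    for la in lev_a:
        for lb in lev_b:
            if np.sum((a == la) & (b == lb)) < 2:
                raise ValueError(f"design cell ({la}, {lb}) has fewer than 2 observations")
    n = len(y)
    Xa = _sum_code(a, lev_a)
    Xb = _sum_code(b, lev_b)
    Xab = np.concatenate(
        [Xa[:, [i]] * Xb[:, [j]] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])],
        axis=1,
    )
    intercept = np.ones((n, 1))
    blocks = {"factor_a": Xa, "factor_b": Xb, "interaction": Xab}
    X_full = np.concatenate([intercept, Xa, Xb, Xab], axis=1)
    df_resid = n - X_full.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    rss_full = _rss(X_full, y)
    ms_resid = rss_full / df_resid
    rows = {}
    for term, block in blocks.items():
        keep = [blk for t, blk in blocks.items() if t != term]
        X_red = np.concatenate([intercept] + keep, axis=1)
        ss = _rss(X_red, y) - rss_full
        ss = max(ss, 0.0)
        df_term = block.shape[1]
        F = (ss / df_term) / ms_resid
        rows[term] = (ss, df_term, F, float(st.f.sf(F, df_term, df_resid)))
    rows["residual"] = (rss_full, df_resid, np.nan, np.nan)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["sum_sq", "df", "F", "p"]
    )


def one_way_anova(values, factor) -> pd.DataFrame:
    """Single-factor ANOVA decomposition (between/within SS, F, p)."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(factor)
    ok = np.isfinite(y)
    y, g = y[ok], g[ok]
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    for lev in levels:
        if np.sum(g == lev) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 observations")
    grand = y.mean()
    ss_between = sum(np.sum(g == lev) * (y[g == lev].mean() - grand) ** 2 for lev in levels)
    ss_within = sum(np.sum((y[g == lev] - y[g == lev].mean()) ** 2) for lev in levels)
    df_b = len(levels) - 1
    df_w = len(y) - len(levels)
    F = (ss_between / df_b) / (ss_within / df_w)
    return pd.DataFrame.from_dict(
        {
            "factor": (ss_between, df_b, F, float(st.f.sf(F, df_b, df_w))),
            "residual": (ss_within, df_w, np.nan, np.nan),
        },
        orient="index",
        columns=["sum_sq", "df", "F", "p"],
    )


# ---------------------------------------------------------------------------
# two-sample tests


def welch_t(x, y, label_a: str = "a", label_b: str = "b") -> PairwiseResult:
    """Unequal-variance t-test with Welch-Satterthwaite df, two-sided."""
    x, y = _as_clean(x), _as_clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = st.ttest_ind(x, y, equal_var=False)
    return PairwiseResult(
        group_a=label_a,
        group_b=label_b,
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        welch_applied=True,
        mean_difference=float(x.mean() - y.mean()),
    )


def student_t(x, y, label_a: str = "a", label_b: str = "b") -> PairwiseResult:
    """Pooled-variance two-sample t-test, two-sided."""
    x, y = _as_clean(x), _as_clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("student_t needs at least 2 observations per group")
    res = st.ttest_ind(x, y, equal_var=True)
    return PairwiseResult(
        group_a=label_a,
        group_b=label_b,
        statistic=float(res.statistic),
        df=float(len(x) + len(y) - 2),
        p_raw=float(res.pvalue),
        welch_applied=False,
        mean_difference=float(x.mean() - y.mean()),
    )


def variance_f_test(x, y) -> VarianceTestResult:
    """Two-sided F-test: F = s_x^2 / s_y^2 with (n_x-1, n_y-1) df.

    p = 2 * min(lower tail, upper tail), capped at 1.
    """
    x, y = _as_clean(x), _as_clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("variance F-test needs at least 2 observations per group")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        raise ValueError("zero sample variance")
    F = vx / vy
    df1, df2 = len(x) - 1, len(y) - 1
    p = min(1.0, 2.0 * min(st.f.cdf(F, df1, df2), st.f.sf(F, df1, df2)))
    return VarianceTestResult(F=float(F), df1=df1, df2=df2, p_two_sided=float(p))


def bonferroni_pairwise(
    df: pd.DataFrame,
    value_col: str,
    group_col: str = "prenatal",
    stratum_col: str = "environment",
    strata: tuple = ("ST", "UE", "PE"),
    groups: tuple = ("SAL", "VPA"),
) -> list[PairwiseResult]:
    """Within-stratum two-sample SAL-vs-VPA comparisons, Bonferroni corrected.

    For each stratum (environment) an independent two-sample t-test of
    group A vs group B is run; the Welch correction is applied
    automatically when the two-sided variance F-test rejects at 0.05.
    Adjusted p = min(1, m * p_raw) with m the number of strata compared.
    Strata where either group has fewer than 2 observations are skipped
    with a warning.
    """
    results: list[PairwiseResult] = []
    m = len(strata)
    for stratum in strata:
        sub = df[df[stratum_col] == stratum]
        x = _as_clean(pd.to_numeric(sub.loc[sub[group_col] == groups[0], value_col], errors="coerce"))
        y = _as_clean(pd.to_numeric(sub.loc[sub[group_col] == groups[1], value_col], errors="coerce"))
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"stratum {stratum!r}: fewer than 2 observations per group; skipped")
            continue
        try:
            vt = variance_f_test(x, y)
            use_welch = vt.p_two_sided < WELCH_TRIGGER_ALPHA
        except ValueError:
            use_welch = False
        test = welch_t if use_welch else student_t
        res = test(x, y, label_a=f"{groups[0]}-{stratum}", label_b=f"{groups[1]}-{stratum}")
        results.append(
            PairwiseResult(
                group_a=res.group_a,
                group_b=res.group_b,
                statistic=res.statistic,
                df=res.df,
                p_raw=res.p_raw,
                p_adjusted=min(1.0, m * res.p_raw),
                correction="bonferroni",
                welch_applied=use_welch,
                mean_difference=res.mean_difference,
            )
        )
    return results


# ---------------------------------------------------------------------------
# exact tests for 2x2 tables


def _check_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer entries")
    return t


def fisher_exact(table) -> ExactTestResult:
    """Conditional (hypergeometric) exact test, two-sided.

    Two-sided p sums the probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one (the
    minimum-likelihood rule). A zero margin gives p = 1 by convention.
    """
    t = _check_table(table)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        warnings.warn("degenerate 2x2 table with a zero margin; p = 1")
        return ExactTestResult(table=tuple(map(tuple, t)), method="fisher", p_two_sided=1.0)
    _, p = st.fisher_exact(t, alternative="two-sided")
    return ExactTestResult(table=tuple(map(tuple, t)), method="fisher", p_two_sided=float(p))


def _wald_scores(n1: int, n2: int) -> np.ndarray:
    """Pooled-proportion Wald score for every possible (x1, x2) table."""
    x1 = np.arange(n1 + 1)[:, None]
    x2 = np.arange(n2 + 1)[None, :]
    p1 = x1 / n1
    p2 = x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (p1 - p2) / np.sqrt(var)
    T[~np.isfinite(T)] = 0.0  # all-success or all-failure tables carry no signal
    return T


def barnard_exact(table, grid_step: float = 0.001) -> ExactTestResult:
    """Unconditional exact test with the pooled-proportion Wald score.

    Group sizes are the row totals; the score is T = (p1 - p2) /
    sqrt(pp*(1-pp)*(1/n1+1/n2)) with pp the pooled success rate. The
    two-sided p-value is the supremum over the nuisance success
    probability pi (uniform grid on (0,1) with ``grid_step``) of the
    probability, under independent binomials, of all tables at least as
    extreme (|T| >= |T_obs|). The maximizing pi is reported.
    """
    t = _check_table(table)
    (x1, f1), (x2, f2) = t
    n1, n2 = x1 + f1, x2 + f2
    if n1 == 0 or n2 == 0:
        raise ValueError("both group sizes must be positive")
    T = _wald_scores(n1, n2)
    T_obs = T[x1, x2]
    if x1 == 0 and x2 == 0:
        return ExactTestResult(
            table=tuple(map(tuple, t)), method="barnard",
            p_two_sided=1.0, statistic=0.0, pi_sup=np.nan,
        )
    extreme = np.abs(T) >= np.abs(T_obs) - 1e-12
    grid = np.arange(grid_step, 1.0, grid_step)
    k1 = np.arange(n1 + 1)
    k2 = np.arange(n2 + 1)
    # binomial pmfs for every grid pi: shapes (G, n+1)
    pmf1 = st.binom.pmf(k1[None, :], n1, grid[:, None])
    pmf2 = st.binom.pmf(k2[None, :], n2, grid[:, None])
    # P(extreme | pi) = sum over extreme cells of pmf1[x1] * pmf2[x2]
    probs = np.einsum("gi,gj,ij->g", pmf1, pmf2, extreme.astype(float))
    best = int(np.argmax(probs))
    return ExactTestResult(
        table=tuple(map(tuple, t)),
        method="barnard",
        p_two_sided=float(min(1.0, probs[best])),
        statistic=float(T_obs),
        pi_sup=float(grid[best]),
    )


# ---------------------------------------------------------------------------
# rank correlation


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mean ranks for ties, two-sided p.

    Pairwise-complete: pairs with a missing value in either vector are
    dropped; at least 4 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("spearman_rho needs at least 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = st.spearmanr(x, y)
    return float(rho), float(p)
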