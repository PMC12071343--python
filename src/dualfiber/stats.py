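"""The statistical battery used by the pipeline, with exact small-sample behavior.

Every test returns a :class:`StatResult`.  Nonparametric tests use exact null
distributions at small n (verifiable by brute-force enumeration) and
tie-corrected normal approximations otherwise.  Multiple-comparison control is
the two-stage linear step-up FDR of Benjamini, Krieger & Yekutieli; outlier
removal in behavioral summaries uses the ROUT construction specialized to a
mean-only model.  Where a decision between a t test and its rank analogue is
gated on normality, the Shapiro-Wilk gate (alpha = 0.05) is exposed so the
full decision path is reproducible, not just the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple
    q_value: float | None = None
    effect_direction: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank vs zero
# ---------------------------------------------------------------------------

EXACT_WILCOXON_MAX_N = 25


def _signed_rank_statistic(values: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ with midranks on |values| (zeros removed upstream)."""
    ranks = sstats.rankdata(np.abs(values))
    return float(ranks[values > 0].sum()), ranks


def _exact_signed_rank_sf(w_plus: float, ranks: np.ndarray) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under random sign flips, exact with ties.

    Midranks are doubled to integers; the null distribution of the doubled
    statistic is built by dynamic-programming convolution over sign choices.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        dist[r:] = dist[r:] + dist[:-r] if r > 0 else 2 * dist[r:]
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    lo = float(dist[: w2 + 1].sum())
    hi = float(dist[w2:].sum())
    return lo, hi


def wilcoxon_signed_rank_vs_zero(values) -> StatResult:
    """Two-sided one-sample Wilcoxon signed-rank test against zero.

    Zeros are removed before ranking.  Exact null distribution for n <= 25
    (ties handled via doubled midranks); tie-corrected normal approximation
    above.
    """
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    n = v.size
    if n < 1:
        raise ValueError("all values are zero; signed-rank test undefined")
    w_plus, ranks = _signed_rank_statistic(v)
    if n <= EXACT_WILCOXON_MAX_N:
        lo, hi = _exact_signed_rank_sf(w_plus, ranks)
        p = min(1.0, 2 * min(lo, hi))
    else:
        mean = n * (n + 1) / 4
        # tie correction on the variance from tied |value| groups
        _, counts = np.unique(np.abs(v), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(counts**3 - counts) / 48
        z = (w_plus - mean) / np.sqrt(var)
        p = float(2 * sstats.norm.sf(abs(z)))
    direction = "positive" if np.median(v) > 0 else "negative"
    return StatResult("wilcoxon_signed_rank", w_plus, p, (n,), effect_direction=direction)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

EXACT_MW_MAX_MIN_N = 8


def mann_whitney(x, y) -> StatResult:
    """Two-sided Mann-Whitney U: exact when min(n) <= 8 and no ties, else the
    tie-corrected normal approximation (scipy provides both branches)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = (
        "exact" if (min(x.size, y.size) <= EXACT_MW_MAX_MIN_N and not has_ties)
        else "asymptotic"
    )
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = "x_greater" if np.median(x) > np.median(y) else "y_greater"
    return StatResult(
        "mann_whitney", float(res.statistic), float(res.pvalue),
        (x.size, y.size), effect_direction=direction, extra={"method": method},
    )


# ---------------------------------------------------------------------------
# F test for equality of variances
# ---------------------------------------------------------------------------

def variance_f_test(x, y) -> StatResult:
    """F = larger sample variance / smaller; two-sided p = doubled upper tail
    capped at 1 (the convention of the original analysis tool)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in each group for a variance F test")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if min(vx, vy) == 0:
        raise ValueError("zero variance in denominator group")
    if vx >= vy:
        f, dfn, dfd = vx / vy, x.size - 1, y.size - 1
        direction = "x_more_variable"
    else:
        f, dfn, dfd = vy / vx, y.size - 1, x.size - 1
        direction = "y_more_variable"
    p = min(1.0, 2 * float(sstats.f.sf(f, dfn, dfd)))
    return StatResult(
        "variance_f_test", float(f), p, (x.size, y.size),
        effect_direction=direction, extra={"dfn": dfn, "dfd": dfd},
    )


# ---------------------------------------------------------------------------
# One-way repeated-measures ANOVA over epochs
# ---------------------------------------------------------------------------

def rm_anova_epochs(epoch_matrix, epoch_names=("baseline", "loom", "post"),
                    alpha: float = 0.05) -> StatResult:
    """Within-trial one-way RM ANOVA across epochs, plus FDR-corrected
    pairwise post hoc paired t contrasts.

    ``epoch_matrix`` is (n_trials, k) with one column per epoch; rows with a
    missing epoch are dropped (a complete triplet is required per trial).
    Post hoc results are attached under ``extra['posthoc']`` with BKY q-values.
    """
    m = np.asarray(epoch_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != len(epoch_names):
        raise ValueError(f"epoch matrix must be (n_trials, {len(epoch_names)})")
    complete = np.all(np.isfinite(m), axis=1)
    n_dropped = int((~complete).sum())
    m = m[complete]
    n, k = m.shape
    if n < 2:
        raise ValueError("need at least two complete trials")
    grand = m.mean()
    ss_treat = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_treat - ss_subj
    df_treat = k - 1
    df_err = (k - 1) * (n - 1)
    ms_treat = ss_treat / df_treat
    ms_err = ss_err / df_err
    if ms_err > 0:
        f = ms_treat / ms_err
    else:
        f = 0.0 if np.isclose(ms_treat, 0) else np.inf
    p = float(sstats.f.sf(f, df_treat, df_err)) if np.isfinite(f) else 0.0

    contrasts = []
    pvals = []
    for i in range(k):
        for j in range(i + 1, k):
            d = m[:, i] - m[:, j]
            if np.allclose(d, d[0]):
                # degenerate constant difference: p undefined unless zero
                pv = 1.0 if np.allclose(d, 0) else 0.0
                tstat = np.inf if not np.allclose(d, 0) else 0.0
            else:
                tstat, pv = sstats.ttest_rel(m[:, i], m[:, j])
            contrasts.append(
                {"contrast": f"{epoch_names[i]}_vs_{epoch_names[j]}",
                 "t": float(tstat), "p": float(pv),
                 "mean_diff": float(d.mean())}
            )
            pvals.append(float(pv))
    qvals, rejected, m0 = bky_fdr(pvals, alpha=alpha)
    for c, q, rej in zip(contrasts, qvals, rejected):
        c["q"] = float(q)
        c["significant"] = bool(rej)
    return StatResult(
        "rm_anova_epochs", float(f), p, (n, k),
        extra={
            "df": (df_treat, df_err),
            "ss": {"treatment": float(ss_treat), "subject": float(ss_subj),
                   "error": float(ss_err)},
            "posthoc": contrasts,
            "n_dropped_incomplete": n_dropped,
        },
    )


# ---------------------------------------------------------------------------
# Two-stage BKY linear step-up FDR
# ---------------------------------------------------------------------------

def _bh_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up procedure at the given level."""
    m = p_sorted.size
    thresh = level * np.arange(1, m + 1) / m
    passing = np.nonzero(p_sorted <= thresh)[0]
    return 0 if passing.size == 0 else int(passing[-1]) + 1


def bky_fdr(p_values, alpha: float = 0.05):
    """Two-stage linear step-up FDR (Benjamini-Krieger-Yekutieli 2006).

    Stage 1 runs the linear step-up procedure at alpha' = alpha/(1+alpha) to
    estimate the number of true nulls m0 = m - r1; stage 2 reruns it at
    alpha' * m / m0.  Returns (q_values, rejected, m0_estimate); q-values are
    the adaptive step-up adjustment p * m0 * (1+alpha) / rank, monotonized and
    capped at 1, so q <= alpha coincides with stage-2 rejection.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool), 0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    alpha_prime = alpha / (1 + alpha)
    r1 = _bh_rejections(p_sorted, alpha_prime)
    if r1 == 0:
        m0 = m
        rejected_sorted = np.zeros(m, dtype=bool)
        scale = m0 * (1 + alpha)
    elif r1 == m:
        m0 = 0
        rejected_sorted = np.ones(m, dtype=bool)
        scale = 1.0  # every test rejected; q-values from plain BH scale
    else:
        m0 = m - r1
        r2 = _bh_rejections(p_sorted, alpha_prime * m / m0)
        rejected_sorted = np.zeros(m, dtype=bool)
        rejected_sorted[:r2] = True
        scale = m0 * (1 + alpha)
    q_sorted = p_sorted * scale / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    rejected = np.empty(m, dtype=bool)
    q[order] = q_sorted
    rejected[order] = rejected_sorted
    return q, rejected, m0


# ---------------------------------------------------------------------------
# ROUT outlier removal (mean-only model)
# ---------------------------------------------------------------------------

def rout_outliers(values, q: float = 0.01):
    """Robust outlier removal at FDR ~= Q, specialized to a constant model.

    Location is the median; scale is the robust standard deviation of the
    residuals (RSDR): the 68.27th percentile of |residuals| inflated by
    sqrt(N/(N-K)) with K = 1 fitted parameter.  Standardized residuals get
    two-tailed t p-values (N-K df) and outliers are the largest-residual
    prefix passing the linear step-up test at rate Q.  Returns
    (kept, removed) as arrays; n < 3 is a no-op.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 3:
        return v.copy(), np.array([])
    resid = v - np.median(v)
    abs_resid = np.abs(resid)
    p68 = np.percentile(abs_resid, 68.27)
    if p68 == 0:
        return v.copy(), np.array([])
    rsdr = p68 * np.sqrt(n / (n - 1))
    t = abs_resid / rsdr
    pvals = 2 * sstats.t.sf(t, df=n - 1)
    order = np.argsort(pvals, kind="stable")      # most extreme first
    thresh = q * np.arange(1, n + 1) / n
    passing = np.nonzero(pvals[order] <= thresh)[0]
    n_out = 0 if passing.size == 0 else int(passing[-1]) + 1
    outlier_mask = np.zeros(n, dtype=bool)
    outlier_mask[order[:n_out]] = True
    return v[~outlier_mask], v[outlier_mask]


# ---------------------------------------------------------------------------
# Two-way ANOVA (type-II sums of squares)
# ---------------------------------------------------------------------------

def _cell_design(fa: np.ndarray, fb: np.ndarray):
    """Full-rank effect-coded design columns for two two-level-or-more factors."""

    def effect_code(f):
        levels = np.unique(f)
        cols = []
        for lev in levels[:-1]:
            c = np.where(f == lev, 1.0, 0.0) - np.where(f == levels[-1], 1.0, 0.0)
            cols.append(c)
        return np.column_stack(cols) if cols else np.empty((f.size, 0))

    a_cols = effect_code(fa)
    b_cols = effect_code(fb)
    ab_cols = (
        np.einsum("ij,ik->ijk", a_cols, b_cols).reshape(fa.size, -1)
        if a_cols.shape[1] and b_cols.shape[1]
        else np.empty((fa.size, 0))
    )
    return a_cols, b_cols, ab_cols


def _sse(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    X = np.column_stack([np.ones(y.size)] + [b for b in blocks if b.shape[1]])
    _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = X @ np.linalg.lstsq(X, y, rcond=None)[0]
    return float(np.sum((y - fit) ** 2))


def two_way_anova(values, factor_a, factor_b,
                  names: tuple[str, str] = ("sex", "familiarity"),
                  alpha: float = 0.05) -> dict[str, StatResult]:
    """Two-way ANOVA with type-II sums of squares (robust to unbalanced cells)
    and BKY-corrected pairwise cell comparisons as post hoc.

    Returns a dict with keys ``names[0]``, ``names[1]``, ``interaction``.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    degenerate = np.ptp(y) == 0  # constant response: every F is 0 by convention
    cells = {}
    for la in np.unique(fa):
        for lb in np.unique(fb):
            mask = (fa == la) & (fb == lb)
            if mask.sum() < 2:
                raise ValueError(f"cell ({la}, {lb}) has fewer than 2 observations")
            cells[(la, lb)] = y[mask]
    a_cols, b_cols, ab_cols = _cell_design(fa, fb)
    sse_full = _sse(y, [a_cols, b_cols, ab_cols])
    sse_ab = _sse(y, [a_cols, b_cols])
    sse_a = _sse(y, [a_cols])
    sse_b = _sse(y, [b_cols])
    df_a = a_cols.shape[1]
    df_b = b_cols.shape[1]
    df_ab = ab_cols.shape[1]
    df_err = y.size - 1 - df_a - df_b - df_ab
    ms_err = sse_full / df_err
    results: dict[str, StatResult] = {}
    for key, ss, df in (
        (names[0], sse_b - sse_ab, df_a),     # SS(A | B)
        (names[1], sse_a - sse_ab, df_b),     # SS(B | A)
        ("interaction", sse_ab - sse_full, df_ab),
    ):
        ss = max(ss, 0.0)
        if degenerate:
            f = 0.0
        elif ms_err > 0:
            f = (ss / df) / ms_err
        else:
            f = 0.0 if np.isclose(ss, 0) else np.inf
        p = float(sstats.f.sf(f, df, df_err)) if np.isfinite(f) else 0.0
        results[key] = StatResult(
            f"two_way_anova[{key}]", float(f), p, (y.size,),
            extra={"ss": float(ss), "df": (df, df_err)},
        )
    # post hoc: all pairwise cell comparisons, FDR-corrected
    keys = sorted(cells)
    comps, pvals = [], []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            ci, cj = cells[keys[i]], cells[keys[j]]
            if np.ptp(ci) == 0 and np.ptp(cj) == 0:  # two constant cells
                t, pv = (0.0, 1.0) if ci[0] == cj[0] else (np.inf, 0.0)
            else:
                t, pv = sstats.ttest_ind(ci, cj)
            if not np.isfinite(pv):
                t, pv = 0.0, 1.0
            comps.append({"cells": (keys[i], keys[j]), "t": float(t), "p": float(pv)})
            pvals.append(float(pv))
    qv, rej, _ = bky_fdr(pvals, alpha=alpha)
    for c, qq, rr in zip(comps, qv, rej):
        c["q"] = float(qq)
        c["significant"] = bool(rr)
    for r in results.values():
        r.extra["posthoc"] = comps
    return results


# ---------------------------------------------------------------------------
# Chi-square on a count table
# ---------------------------------------------------------------------------

def chi_square_counts(count_table) -> StatResult:
    """Pearson chi-square on an r x k count table, no continuity correction."""
    table = np.asarray(count_table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise ValueError("count table must contain nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("count table has a zero marginal")
    chi2, p, dof, _ = sstats.chi2_contingency(table, correction=False)
    return StatResult(
        "chi_square", float(chi2), float(p),
        tuple(int(s) for s in table.sum(axis=1)), extra={"df": int(dof)},
    )


# ---------------------------------------------------------------------------
# Normality-gated comparisons (decision path of the original analysis)
# ---------------------------------------------------------------------------

def shapiro_normal(values, alpha: float = 0.05) -> bool:
    v = np.asarray(values, dtype=float)
    if v.size < 3 or np.ptp(v) == 0:
        return False
    return float(sstats.shapiro(v).pvalue) >= alpha


def paired_comparison(x, y, auto_normality: bool = True) -> StatResult:
    """Paired t test when the differences pass Shapiro-Wilk, else Wilcoxon."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if auto_normality and shapiro_normal(d):
        t, p = sstats.ttest_rel(x, y)
        res = StatResult("paired_t", float(t), float(p), (x.size,))
        res.extra["auto_selected"] = "paired_t (differences normal)"
        return res
    res = wilcoxon_signed_rank_vs_zero(d)
    res.extra["auto_selected"] = "wilcoxon (differences non-normal)"
    return res


def unpaired_comparison(x, y, auto_normality: bool = True) -> StatResult:
    """Unpaired t test when both groups pass Shapiro-Wilk, else Mann-Whitney."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if auto_normality and shapiro_normal(x) and shapiro_normal(y):
        t, p = sstats.ttest_ind(x, y)
        res = StatResult("unpaired_t", float(t), float(p), (x.size, y.size))
        res.extra["auto_selected"] = "unpaired_t (both groups normal)"
        return res
    res = mann_whitney(x, y)
    res.extra["auto_selected"] = "mann_whitney (non-normal group)"
    return res
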