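"""Two-group differential abundance statistics and metadata correlation.

The workhorse is the two-sided Mann-Whitney U test, preferred for abundance
data because relative abundances are rarely normal. U counts the pairs
(x_i, y_j) with x_i > y_j (ties counted half). For small tie-free samples
(n + m <= 20) the p-value is exact, from the full null distribution of U
computed by the standard counting recursion; otherwise a normal
approximation with tie correction and continuity correction is used.

Student's t (pooled, with Welch behind a flag) is available as the
parametric alternative, alongside advisory normality (Shapiro-Wilk) and
variance-homogeneity (Bartlett, mean-centered Levene) diagnostics; the
diagnostics never switch the chosen test automatically.

Raw p-values across features are corrected once per comparison with either
Bonferroni or the Benjamini-Hochberg step-up FDR procedure, and results can
be filtered jointly on adjusted p, absolute fold change max(FC, 1/FC) and
mean relative abundance. Numerical metadata can be correlated per feature
(Spearman by default) with the same multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import AbundanceTable
from .errors import UsageError, ValidationError
from .metadata import SampleGroups, SampleMetadata

__all__ = [
    "MannWhitneyResult",
    "TTestResult",
    "DiagnosticsReport",
    "mann_whitney",
    "t_test",
    "normality_and_variance_diagnostics",
    "adjust_pvalues",
    "compare_groups",
    "filter_results",
    "correlate_with_metadata",
    "write_results",
]

#: largest combined sample size for which the exact U null distribution is used
EXACT_THRESHOLD = 20


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U of the first group
    pvalue: float
    exact: bool


@lru_cache(maxsize=None)
def _u_null_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of tie-free labelings with each U value, group sizes n and m.

    ``counts[u]`` is the number of partitions of u into at most n parts each
    at most m (the coefficient of q^u in the Gaussian binomial
    [n+m choose n]_q), via the recursion G(n, m) = G(n, m-1) + q^m G(n-1, m).
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_null_counts(n, m - 1)  # all parts <= m-1
    b = _u_null_counts(n - 1, m)  # one part equal to m removed
    out = [0] * (n * m + 1)
    for u in range(n * m + 1):
        v = a[u] if u < len(a) else 0
        if u >= m and u - m < len(b):
            v += b[u - m]
        out[u] = v
    return tuple(out)


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test; U is counted for the first group."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise UsageError("Mann-Whitney requires at least one observation per group")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r_x = ranks[:n].sum()
    u = r_x - n * (n + 1) / 2.0  # = #{x_i > y_j} + 0.5 * ties

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = (tie_counts > 1).any()

    if not has_ties and n + m <= EXACT_THRESHOLD:
        counts = np.asarray(_u_null_counts(n, m), dtype=float)
        total = counts.sum()
        u_int = int(round(u))
        lo = min(u_int, n * m - u_int)  # symmetric null distribution
        p = min(1.0, 2.0 * counts[: lo + 1].sum() / total)
        return MannWhitneyResult(float(u), float(p), exact=True)

    # normal approximation, tie-corrected sigma, continuity correction
    big_n = n + m
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (big_n * (big_n - 1))
    sigma2 = n * m / 12.0 * ((big_n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return MannWhitneyResult(float(u), 1.0, exact=False)
    mu = n * m / 2.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return MannWhitneyResult(float(u), float(p), exact=False)


# ---------------------------------------------------------------------------
# t-test


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    df: float
    degenerate: bool = False  # zero variance with unequal means


def t_test(x, y, variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t-test, pooled-variance by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise UsageError("t-test requires at least two observations per group")
    if variant not in ("pooled", "welch"):
        raise UsageError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        df = len(x) + len(y) - 2.0
        if x.mean() == y.mean():
            return TTestResult(0.0, 1.0, df)
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return TTestResult(sign * np.inf, 0.0, df, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


# ---------------------------------------------------------------------------
# diagnostics


@dataclass(frozen=True)
class DiagnosticsReport:
    """Advisory normality/variance diagnostics; never switches the test."""

    shapiro_w_x: float | None = None
    shapiro_p_x: float | None = None
    shapiro_w_y: float | None = None
    shapiro_p_y: float | None = None
    bartlett_stat: float | None = None
    bartlett_p: float | None = None
    levene_stat: float | None = None
    levene_p: float | None = None
    notes: tuple[str, ...] = ()


def normality_and_variance_diagnostics(x, y) -> DiagnosticsReport:
    """Shapiro-Wilk per group; Bartlett and mean-centered Levene across groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out: dict = {}
    notes: list[str] = []
    for label, arr, wkey, pkey in (
        ("x", x, "shapiro_w_x", "shapiro_p_x"),
        ("y", y, "shapiro_w_y", "shapiro_p_y"),
    ):
        if len(arr) < 3:
            notes.append(f"Shapiro-Wilk unavailable for group {label} (n < 3)")
        elif np.ptp(arr) == 0:
            notes.append(f"Shapiro-Wilk unavailable for group {label} (constant values)")
        else:
            w, p = sps.shapiro(arr)
            out[wkey], out[pkey] = float(w), float(p)
    if len(x) < 2 or len(y) < 2:
        notes.append("variance tests unavailable (n < 2 in a group)")
    else:
        if x.var(ddof=1) == 0 or y.var(ddof=1) == 0:
            notes.append("Bartlett unavailable (zero variance in a group)")
        else:
            stat, p = sps.bartlett(x, y)
            out["bartlett_stat"], out["bartlett_p"] = float(stat), float(p)
        stat, p = sps.levene(x, y, center="mean")
        out["levene_stat"], out["levene_p"] = float(stat), float(p)
    return DiagnosticsReport(notes=tuple(notes), **out)


# ---------------------------------------------------------------------------
# multiple-testing correction


def adjust_pvalues(p_values, method: str = "bh") -> np.ndarray:
    """Adjust a p-value vector for multiple testing.

    ``bonferroni``: min(1, m*p). ``bh``: Benjamini-Hochberg step-up — sort
    ascending, q_(i) = p_(i) * m / i, enforce monotonicity from the largest
    rank down, cap at 1, return in input order. ``none`` passes through.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        bad = p[(p < 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValidationError(f"p-value {bad} outside [0, 1]")
    m = p.size
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "bh":
        raise UsageError(f"method must be 'bonferroni', 'bh' or 'none', got {method!r}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# per-feature comparison


def _fold_change(mean_a: float, mean_b: float, eps: float) -> float:
    if eps == 0.0:
        if mean_a == 0.0 and mean_b == 0.0:
            return 1.0
        if mean_b == 0.0:
            return np.inf
        return mean_a / mean_b
    return (mean_a + eps) / (mean_b + eps)


def default_pseudocount(means_a: np.ndarray, means_b: np.ndarray) -> float:
    """Half the smallest nonzero group mean in the comparison (0 if none)."""
    pooled = np.concatenate([means_a, means_b])
    nonzero = pooled[pooled > 0]
    return float(nonzero.min() / 2.0) if nonzero.size else 0.0


RESULT_COLUMNS = [
    "level_name", "statistic", "p_raw", "p_adj", "fold_change",
    "abs_fold_change", "mean_rel_a", "mean_rel_b", "test", "adjustment",
]


def compare_groups(
    table: AbundanceTable,
    groups: SampleGroups,
    test: str = "mannwhitney",
    adjust: str = "bh",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-feature two-group test on a relative abundance table.

    Returns a DataFrame indexed by feature id with columns
    ``statistic, p_raw, p_adj, fold_change, abs_fold_change, mean_rel_a,
    mean_rel_b, test, adjustment, level_name``, sorted by ascending adjusted
    p (ties broken by feature id). The p-vector is adjusted once across all
    features tested (m = number of features).
    """
    if table.mode != "relative":
        raise UsageError("compare_groups requires a relative table; normalize first")
    if test not in ("mannwhitney", "student", "welch"):
        raise UsageError(f"test must be 'mannwhitney', 'student' or 'welch', got {test!r}")
    for label, samples in ((groups.label_a, groups.samples_a), (groups.label_b, groups.samples_b)):
        missing = [s for s in samples if s not in table.data.columns]
        if missing:
            raise UsageError(f"group {label!r} samples missing from abundance table: {missing}")
    sub_a = table.data[list(groups.samples_a)].to_numpy()
    sub_b = table.data[list(groups.samples_b)].to_numpy()
    means_a = sub_a.mean(axis=1)
    means_b = sub_b.mean(axis=1)
    eps = default_pseudocount(means_a, means_b) if pseudocount is None else float(pseudocount)
    if eps < 0:
        raise UsageError("pseudocount must be non-negative")

    stats_out = np.empty(len(table.feature_ids))
    p_raw = np.empty(len(table.feature_ids))
    for i, (xa, xb) in enumerate(zip(sub_a, sub_b)):
        if test == "mannwhitney":
            res = mann_whitney(xa, xb)
        else:
            res = t_test(xa, xb, variant="pooled" if test == "student" else "welch")
        stats_out[i] = res.statistic
        p_raw[i] = res.pvalue
    p_adj = adjust_pvalues(p_raw, adjust)

    fc = np.array([_fold_change(a, b, eps) for a, b in zip(means_a, means_b)])
    with np.errstate(divide="ignore"):
        abs_fc = np.maximum(fc, np.where(fc > 0, 1.0 / fc, np.inf))
    result = pd.DataFrame(
        {
            "level_name": table.level_name,
            "statistic": stats_out,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "fold_change": fc,
            "abs_fold_change": abs_fc,
            "mean_rel_a": means_a,
            "mean_rel_b": means_b,
            "test": test,
            "adjustment": adjust,
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    result = result.sort_values(["p_adj", "feature_id"], kind="mergesort")
    result.attrs["group_a"] = groups.label_a
    result.attrs["group_b"] = groups.label_b
    result.attrs["pseudocount"] = eps
    return result


def filter_results(
    results: pd.DataFrame,
    p_max: float = 0.05,
    min_abs_fc: float = 1.0,
    min_mean_rel: float = 0.0,
) -> pd.DataFrame:
    """Retain features passing all three thresholds jointly.

    The p threshold applies to adjusted p-values when an adjustment was
    selected, raw p otherwise; the mean-abundance filter passes when either
    group's mean relative abundance reaches ``min_mean_rel``.
    """
    if not 0 < p_max <= 1:
        raise UsageError(f"p_max must be in (0, 1], got {p_max}")
    if min_abs_fc < 1:
        raise UsageError(f"min_abs_fc must be >= 1, got {min_abs_fc}")
    if not 0 <= min_mean_rel < 1:
        raise UsageError(f"min_mean_rel must be in [0, 1), got {min_mean_rel}")
    adjustment = results["adjustment"].iloc[0] if len(results) else "none"
    p_col = "p_raw" if adjustment == "none" else "p_adj"
    keep = (
        (results[p_col] <= p_max)
        & (results["abs_fold_change"] >= min_abs_fc)
        & (results[["mean_rel_a", "mean_rel_b"]].max(axis=1) >= min_mean_rel)
    )
    out = results[keep].copy()
    out.attrs.update(results.attrs)
    out.attrs["filters"] = {
        "p_max": p_max, "p_column": p_col,
        "min_abs_fc": min_abs_fc, "min_mean_rel": min_mean_rel,
    }
    return out


def write_results(results: pd.DataFrame, path_or_buf) -> None:
    """Write a comparison/correlation result table as TSV (deterministic order)."""
    results.to_csv(path_or_buf, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# correlation with numerical metadata


def correlate_with_metadata(
    table: AbundanceTable,
    md: SampleMetadata,
    variable: str,
    method: str = "spearman",
    adjust: str = "bh",
) -> pd.DataFrame:
    """Correlate every feature with a numerical metadata variable.

    Samples with missing metadata are excluded pairwise; features with fewer
    than 3 complete pairs or zero variance are flagged ``unavailable`` and
    excluded from the multiplicity adjustment.
    """
    if table.mode != "relative":
        raise UsageError("correlation requires a relative table; normalize first")
    if method not in ("spearman", "pearson"):
        raise UsageError(f"method must be 'spearman' or 'pearson', got {method!r}")
    values = md.numeric_values(variable)  # raises UsageError on categorical
    shared = [s for s in table.sample_ids if s in values.index]
    if not shared:
        raise UsageError("no shared samples between abundance table and metadata")
    meta = values.loc[shared].to_numpy()
    complete = np.isfinite(meta)

    coefs = np.full(len(table.feature_ids), np.nan)
    p_raw = np.full(len(table.feature_ids), np.nan)
    available = np.zeros(len(table.feature_ids), dtype=bool)
    sub = table.data[shared].to_numpy()
    for i, row in enumerate(sub):
        mask = complete & np.isfinite(row)
        if mask.sum() < 3 or np.ptp(row[mask]) == 0 or np.ptp(meta[mask]) == 0:
            continue
        if method == "spearman":
            r, p = sps.spearmanr(row[mask], meta[mask])
        else:
            r, p = sps.pearsonr(row[mask], meta[mask])
        coefs[i], p_raw[i] = r, p
        available[i] = True
    p_adj = np.full(len(table.feature_ids), np.nan)
    if available.any():
        p_adj[available] = adjust_pvalues(p_raw[available], adjust)
    result = pd.DataFrame(
        {
            "coefficient": coefs,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "n": [int((complete & np.isfinite(r)).sum()) for r in sub],
            "available": available,
            "method": method,
            "adjustment": adjust,
            "variable": variable,
        },
        index=pd.Index(table.feature_ids, name="feature_id"),
    )
    return result.sort_values(["p_adj", "feature_id"], kind="mergesort", na_position="last")
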