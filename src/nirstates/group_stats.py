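"""Group-level inference on channel activation amplitudes, and the
summary-statistic tests used for demographic/clinical tables.

Channel-wise tests: one-sample t activation maps per group, one-way ANOVA
across the three groups with Benjamini-Hochberg FDR over channels, Fisher
LSD post hoc pairwise comparisons, and paired t tests on ROI amplitudes
between the cueing conditions.

Summary-statistic utilities reconstruct pooled-variance t, one-way ANOVA F
and Pearson chi-square statistics from printed group means/SDs/counts, so a
published demographics table can be checked without raw data.  A Wilcoxon
rank-sum wrapper is provided for raw ordinal inputs only — it cannot be
recomputed from medians and quartiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class SummaryStats:
    """Printed per-group summary of a continuous variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be nonnegative")
        if self.n < 2:
            raise ValueError("summary statistics need n >= 2")


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def one_sample_activation(betas: np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Per-channel one-sample t against zero.

    ``betas`` is subjects x channels for one group and condition.  Channels
    with p < alpha are labelled ``activation`` (positive mean) or
    ``deactivation`` (negative mean).  Zero-variance channels get an
    infinite statistic with p = 0 and a warning.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim != 2 or b.shape[0] < 2:
        raise ValueError("need a subjects x channels array with >= 2 subjects")
    n = b.shape[0]
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance channels {np.flatnonzero(degenerate) + 1}: t reported as inf"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(degenerate & (mean != 0), np.sign(mean) * np.inf, t)
    t = np.where(degenerate & (mean == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, 2 * stats.t.sf(np.abs(np.where(np.isinf(t), 0, t)), n - 1))
    p = np.where(degenerate & (mean == 0), 1.0, p)
    direction = np.where(
        p < alpha, np.where(mean > 0, "activation", "deactivation"), "n.s."
    )
    return pd.DataFrame(
        {
            "channel": np.arange(1, b.shape[1] + 1),
            "mean": mean,
            "t": t,
            "p": p,
            "direction": direction,
        }
    )


def anova_across_groups(
    betas_by_group: dict[str, np.ndarray], fdr: bool = True, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-channel one-way ANOVA across groups, optionally BH-FDR corrected.

    Significant channels (q < alpha when ``fdr``, else p < alpha) form the
    ROI set used downstream.
    """
    groups = list(betas_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = []
    for g in groups:
        a = np.asarray(betas_by_group[g], dtype=float)
        if a.ndim != 2 or a.shape[0] < 2:
            raise ValueError(f"group {g!r} needs a subjects x channels array with n >= 2")
        arrays.append(a)
    n_ch = arrays[0].shape[1]
    k = len(arrays)
    N = sum(a.shape[0] for a in arrays)
    grand = np.vstack(arrays).mean(axis=0)
    ssb = sum(a.shape[0] * (a.mean(axis=0) - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean(axis=0)) ** 2).sum(axis=0) for a in arrays)
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 0, F), df1, df2))
    p = np.where((ssw == 0) & (ssb == 0), 1.0, p)
    out = pd.DataFrame(
        {
            "channel": np.arange(1, n_ch + 1),
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
        }
    )
    for g, a in zip(groups, arrays):
        out[f"mean_{g}"] = a.mean(axis=0)
    if fdr:
        out["q"] = fdr_adjust(p)
        out["significant"] = out["q"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def lsd_posthoc(
    betas_by_group: dict[str, np.ndarray], channel: int, anova_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fisher LSD pairwise comparisons for one channel.

    Uses the pooled within-group mean square from the ANOVA with its N-k
    degrees of freedom and applies no further multiplicity correction
    (which is what LSD means).  Intended to follow a significant ANOVA; if
    ``anova_table`` is given, the channel must appear in it.
    """
    if anova_table is not None and channel not in set(anova_table["channel"]):
        raise ValueError(f"channel {channel} has no ANOVA result")
    groups = list(betas_by_group)
    vals = {g: np.asarray(betas_by_group[g], dtype=float)[:, channel - 1] for g in groups}
    k = len(groups)
    N = sum(v.size for v in vals.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in vals.values())
    df = N - k
    mse = ssw / df
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            diff = vals[a].mean() - vals[b].mean()
            se = np.sqrt(mse * (1 / vals[a].size + 1 / vals[b].size))
            if se == 0:
                t_stat, p, flag = np.nan, np.nan, "degenerate (zero MSE)"
            else:
                t_stat = diff / se
                p = 2 * stats.t.sf(abs(t_stat), df)
                flag = ""
            rows.append(
                {
                    "channel": channel,
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": diff,
                    "t": t_stat,
                    "df": df,
                    "p": p,
                    "note": flag,
                }
            )
    return pd.DataFrame(rows)


def paired_ttest_roi(
    beta_no_ras: np.ndarray, beta_ras: np.ndarray
) -> tuple[float, float, float]:
    """Paired t between the two cueing conditions on one ROI.

    Returns (t, two-sided p, mean difference no-RAS minus RAS); degenerate
    zero-variance differences give (nan, nan, diff) with a warning.
    """
    a = np.asarray(beta_no_ras, dtype=float)
    b = np.asarray(beta_ras, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if md == 0:
            return 0.0, 1.0, 0.0
        warnings.warn("zero-variance paired differences; t undefined")
        return float("nan"), float("nan"), float(md)
    t = md / (sd / np.sqrt(d.size))
    p = 2 * stats.t.sf(abs(t), d.size - 1)
    return float(t), float(p), float(md)


def pooled_t_from_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from printed summaries.

    Returns (t, df, p) with df = n1 + n2 - 2.  The pooled (not Welch)
    formula is the default because it is the one that reproduces published
    demographics-table statistics recomputed from their own summaries.
    """
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    se = np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    df = a.n + b.n - 2
    if se == 0:
        return (0.0, df, 1.0) if a.mean == b.mean else (float("inf"), df, 0.0)
    t = (a.mean - b.mean) / se
    return float(t), df, float(2 * stats.t.sf(abs(t), df))


def welch_t_from_summary(a: SummaryStats, b: SummaryStats) -> tuple[float, float, float]:
    """Welch unequal-variance variant, for sensitivity checks."""
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se = np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    t = (a.mean - b.mean) / se
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def anova_from_summary(groups: list[SummaryStats]) -> tuple[float, int, int, float]:
    """One-way ANOVA F reconstructed from group means, SDs and sizes.

    Exactly equals the raw-data ANOVA when the summaries are exact.
    Returns (F, df1, df2, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    N = sum(g.n for g in groups)
    k = len(groups)
    grand = sum(g.n * g.mean for g in groups) / N
    ssb = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ssw = sum((g.n - 1) * g.sd**2 for g in groups)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        return (0.0, df1, df2, 1.0) if ssb == 0 else (float("inf"), df1, df2, 0.0)
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2, float(stats.f.sf(F, df1, df2))


def chi_square_counts(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table, no continuity correction.

    Returns (chi2, df, p).
    """
    T = np.asarray(table, dtype=float)
    if np.any(T < 0) or not np.allclose(T, np.round(T)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("zero row/column margin; chi-square undefined")
    chi2, p, df, _ = stats.chi2_contingency(T, correction=False)
    return float(chi2), int(df), float(p)


def ranksum_raw(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum z statistic for raw ordinal data (e.g. disease
    stage).  Not computable from printed medians/quartiles."""
    z, p = stats.ranksums(x, y)
    return float(z), float(p)


def select_rois(anova_table: pd.DataFrame) -> list[int]:
    """Channels significant in the across-group ANOVA define the ROI set."""
    return sorted(anova_table.loc[anova_table["significant"], "channel"].astype(int))
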