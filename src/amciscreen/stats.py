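"""Sequential group-comparison statistics and cross-modal correlations.

Each feature is compared between groups through a decision ladder:

1. normality of both samples (Lilliefors-corrected Kolmogorov–Smirnov,
   i.e. KS against a Gaussian with sample-estimated mean/SD);
2. if either sample is non-normal → a rank test (Mann–Whitney rank-sum by
   default; a literal signed-rank mode pairing equal-n groups by sorted
   order is available for fidelity with the original report);
3. if both normal → Levene's test (mean-centered) for equal variances;
4. equal variances → independent-samples t-test, unequal → Welch's t-test.

p-values are corrected per analysis family with the Benjamini–Hochberg
step-up procedure. Behavioral×neurological relationships use Pearson
correlations with BH correction over the whole pair grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    """Outcome of one group comparison, including the decision path taken."""

    feature_name: str
    test_used: str            # independent-t | welch-t | wilcoxon
    statistic: float
    p_raw: float
    p_adjusted: float | None
    normality_p: float
    variance_p: float | None  # absent when the rank branch was taken


def compare_groups(
    values_a,
    values_b,
    alpha: float = 0.05,
    rank_mode: str = "mannwhitney",
    feature_name: str = "",
) -> StatResult:
    """Run the sequential ladder on two independent samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample must have at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("degenerate (constant) sample")

    norm_p = min(lilliefors(a, dist="norm")[1], lilliefors(b, dist="norm")[1])
    if norm_p < alpha:
        if rank_mode == "mannwhitney":
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        elif rank_mode == "signedrank":
            if len(a) != len(b):
                raise ValueError("signed-rank mode requires equal group sizes")
            stat, p = sps.wilcoxon(np.sort(a), np.sort(b))
        else:
            raise ValueError(f"unknown rank_mode {rank_mode!r}")
        return StatResult(feature_name, "wilcoxon", float(stat), float(p),
                          None, float(norm_p), None)

    var_stat, var_p = sps.levene(a, b, center="mean")
    equal_var = var_p >= alpha
    stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    test = "independent-t" if equal_var else "welch-t"
    return StatResult(feature_name, test, float(stat), float(p),
                      None, float(norm_p), float(var_p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_feature_table(
    table: pd.DataFrame,
    features,
    group_col: str = "group",
    groups: tuple[str, str] = ("HC", "aMCI"),
    alpha: float = 0.05,
    rank_mode: str = "mannwhitney",
) -> pd.DataFrame:
    """Ladder comparison for each feature, BH-corrected within this family.

    Returns one row per feature with group means/SDs, the test chosen by
    the decision path, and raw/adjusted p-values.
    """
    a_mask = table[group_col] == groups[0]
    b_mask = table[group_col] == groups[1]
    results = [
        compare_groups(table.loc[a_mask, f], table.loc[b_mask, f],
                       alpha=alpha, rank_mode=rank_mode, feature_name=f)
        for f in features
    ]
    adjusted = bh_adjust([r.p_raw for r in results])
    results = [replace(r, p_adjusted=float(p)) for r, p in zip(results, adjusted)]
    return pd.DataFrame({
        "feature": [r.feature_name for r in results],
        f"mean_{groups[0]}": [table.loc[a_mask, r.feature_name].mean() for r in results],
        f"sd_{groups[0]}": [table.loc[a_mask, r.feature_name].std(ddof=1) for r in results],
        f"mean_{groups[1]}": [table.loc[b_mask, r.feature_name].mean() for r in results],
        f"sd_{groups[1]}": [table.loc[b_mask, r.feature_name].std(ddof=1) for r in results],
        "test_used": [r.test_used for r in results],
        "statistic": [r.statistic for r in results],
        "p_raw": [r.p_raw for r in results],
        "p_adjusted": [r.p_adjusted for r in results],
    })


def cross_modal_correlations(
    behavioral: pd.DataFrame,
    neurological: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r for every behavioral × neurological column pair.

    Returns ``(r, p_adjusted)`` DataFrames indexed by behavioral feature ×
    neurological feature; p-values are BH-corrected jointly over the grid.
    """
    if len(behavioral) != len(neurological):
        raise ValueError("tables must describe the same subjects")
    if len(behavioral) < 3:
        raise ValueError("need at least 3 paired observations")
    for df in (behavioral, neurological):
        zero_var = [c for c in df.columns if np.ptp(df[c].to_numpy(dtype=float)) == 0]
        if zero_var:
            raise ValueError(f"zero-variance columns: {zero_var}")

    r = pd.DataFrame(index=behavioral.columns, columns=neurological.columns, dtype=float)
    p = r.copy()
    for bcol in behavioral.columns:
        for ncol in neurological.columns:
            res = sps.pearsonr(behavioral[bcol], neurological[ncol])
            r.loc[bcol, ncol] = res.statistic
            p.loc[bcol, ncol] = res.pvalue
    p_adj = pd.DataFrame(
        bh_adjust(p.to_numpy().ravel()).reshape(p.shape),
        index=p.index, columns=p.columns,
    )
    return r, p_adj
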