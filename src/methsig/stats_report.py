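"""Group-level statistics: feature enrichment, beta strata, expression links.

These reports compare feature abundance between site classes (e.g. DMS+ vs
DMS-, or high- vs low-methylation strata), and relate the genomic index to
differential gene expression.  Two-sided tests only; Welch's t-test is the
default with a Mann-Whitney switch — the caller chooses, no automatic
normality gating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BetaMatrix

__all__ = [
    "GroupComparison",
    "ExpressionLink",
    "IndexExpressionResult",
    "stratify_by_beta",
    "compare_feature_groups",
    "index_vs_expression",
    "summarize_table1",
]


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ExpressionLink:
    """One DMS mapped to a gene's differential expression (log2 fold change)."""

    site_id: str
    gene: str
    log2fc: float
    genomic_index: float


@dataclass(frozen=True)
class IndexExpressionResult:
    mean_index_high: float
    mean_index_low: float
    p_value: float
    slope: float
    intercept: float
    r_value: float
    split_value: float


def stratify_by_beta(
    matrix: BetaMatrix,
    low_max: float = 0.1,
    high_min: float = 0.9,
    group: str | None = None,
) -> tuple[list[str], list[str]]:
    """Split sites into unmethylated (mean beta <= low_max) and methylated
    (mean beta >= high_min) sets; intermediate sites are excluded.

    Means are taken over the samples of ``group`` when given, else over all
    samples.
    """
    if not low_max < high_min:
        raise ValueError("low_max must be strictly below high_min")
    if group is not None:
        cols = matrix.group_samples(group)
        if not cols:
            raise ValueError(f"no samples in group {group!r}")
        vals = matrix.values[cols]
    else:
        vals = matrix.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = vals.mean(axis=1, skipna=True)
    low = [str(s) for s in means.index[means <= low_max]]
    high = [str(s) for s in means.index[means >= high_min]]
    if not low and not high:
        warnings.warn("all sites have intermediate methylation; both strata empty",
                      stacklevel=2)
    return low, high


def compare_feature_groups(
    features_a: Sequence[float] | np.ndarray,
    features_b: Sequence[float] | np.ndarray,
    feature_name: str = "feature",
    test: Literal["t", "wilcoxon"] = "t",
) -> GroupComparison:
    """Two-sided comparison of a per-site feature between two site groups.

    ``test="t"`` runs Welch's t-test, ``"wilcoxon"`` the Mann-Whitney rank
    test.  When both groups have zero variance the t-test is degenerate and p
    is defined as 1 with a warning (identical constants carry no evidence).
    """
    a = np.asarray(features_a, dtype=float)
    b = np.asarray(features_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test == "t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            warnings.warn("zero variance in both groups; p defined as 1",
                          stacklevel=2)
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        test_name = "welch_t"
    elif test == "wilcoxon":
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        test_name = "mann_whitney"
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        feature=feature_name,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        test=test_name, p_value=min(p, 1.0),
    )


def index_vs_expression(
    links: Sequence[ExpressionLink] | pd.DataFrame,
    split: Literal["median", "threshold"] = "median",
    threshold: float | None = None,
) -> IndexExpressionResult:
    """Association between the genomic index and |log2 fold change|.

    Sites are split into high/low |log2FC| groups (at the median by default,
    or at an explicit threshold); a two-sided t-test compares the genomic
    index between groups, and an ordinary least-squares fit of |log2FC| on
    the genomic index gives the slope/intercept.  With a constant index the
    slope is undefined and reported as NaN.
    """
    if isinstance(links, pd.DataFrame):
        df = links
        idx = df["genomic_index"].to_numpy(dtype=float)
        fc = df["log2fc"].to_numpy(dtype=float)
    else:
        idx = np.array([l.genomic_index for l in links], dtype=float)
        fc = np.array([l.log2fc for l in links], dtype=float)
    if idx.size < 4:
        raise ValueError("at least 4 expression links required")
    abs_fc = np.abs(fc)
    if split == "median":
        cut = float(np.median(abs_fc))
    elif split == "threshold":
        if threshold is None:
            raise ValueError("threshold split requires a threshold value")
        cut = float(threshold)
    else:
        raise ValueError(f"unknown split {split!r}")
    high = idx[abs_fc > cut]
    low = idx[abs_fc <= cut]
    if high.size >= 2 and low.size >= 2:
        if np.ptp(high) == 0 and np.ptp(low) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(high, low, equal_var=False).pvalue)
    else:
        p = float("nan")
    if np.ptp(idx) == 0:
        slope = intercept = r = float("nan")
    else:
        fit = stats.linregress(idx, abs_fc)
        slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    return IndexExpressionResult(
        mean_index_high=float(high.mean()) if high.size else float("nan"),
        mean_index_low=float(low.mean()) if low.size else float("nan"),
        p_value=p, slope=slope, intercept=intercept, r_value=r, split_value=cut,
    )


def summarize_table1(
    dms_plus_features: pd.DataFrame,
    dms_minus_features: pd.DataFrame,
    feature_columns: Sequence[str] | None = None,
    test: Literal["t", "wilcoxon"] = "t",
) -> pd.DataFrame:
    """Per-feature mean(sd) of the DMS+ and DMS- classes with test p-values.

    When ``gc`` / ``cpg_oe`` columns are present they are summarised too, so
    one call yields the full per-dataset row schema: feature, mean_plus,
    sd_plus, mean_minus, sd_minus, p_value, test, n_plus, n_minus.
    """
    if dms_plus_features.empty or dms_minus_features.empty:
        raise ValueError("both classes must be nonempty")
    if feature_columns is None:
        candidates = ["g4", "pals", "tfbs", "ctfbs", "altspl_count", "gc", "cpg_oe"]
        feature_columns = [
            c for c in candidates
            if c in dms_plus_features.columns and c in dms_minus_features.columns
        ]
    rows = []
    for col in feature_columns:
        cmp = compare_feature_groups(
            dms_plus_features[col].dropna(), dms_minus_features[col].dropna(),
            feature_name=col, test=test,
        )
        rows.append({
            "feature": col,
            "mean_plus": cmp.mean_a, "sd_plus": cmp.sd_a,
            "mean_minus": cmp.mean_b, "sd_minus": cmp.sd_b,
            "p_value": cmp.p_value, "test": cmp.test,
            "n_plus": cmp.n_a, "n_minus": cmp.n_b,
        })
    return pd.DataFrame(rows, columns=[
        "feature", "mean_plus", "sd_plus", "mean_minus", "sd_minus",
        "p_value", "test", "n_plus", "n_minus",
    ])
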