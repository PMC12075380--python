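"""Group contrasts, pre/post comparisons, brain-behavior correlations and
Benjamini-Hochberg FDR control.

Test selection follows the convention: rank tests (Mann-Whitney U) for
non-normal data, Student's t for normal data, with an automatic
Shapiro-Wilk gate at alpha = 0.05 per group; paired t-tests for pre/post
contrasts; Pearson's chi-squared for categorical tables; Spearman
correlations for brain-behavior relationships. All tests are two-sided.
Adjusted p-values are computed within analysis families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["ContrastSpec", "run_contrast", "bh_fdr", "correlate_change"]

TESTS = ("mann_whitney", "two_sample_t", "paired_t", "chi_square", "spearman")


@dataclass
class ContrastSpec:
    """One planned comparison.

    ``test`` may be any of mann_whitney / two_sample_t / paired_t /
    chi_square / spearman, or "auto" to gate between mann_whitney and
    two_sample_t by a Shapiro-Wilk normality check (alpha = 0.05 per
    group).
    """

    name: str
    test: str = "auto"
    family: str = "default"
    alpha_normality: float = 0.05

    def __post_init__(self) -> None:
        if self.test not in TESTS + ("auto",):
            raise ValueError(f"unknown test {self.test!r}")


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    d = np.mean(a) - np.mean(b)
    return "positive" if d > 0 else ("negative" if d < 0 else "zero")


def run_contrast(
    spec: ContrastSpec,
    x: np.ndarray,
    y: np.ndarray,
) -> dict:
    """Run one contrast on two samples (or paired vectors / a 2-D table
    for chi_square; (x, y) value pairs for spearman).

    Returns a result row: contrast, test, statistic, p_raw, n, direction.
    """
    x = np.asarray(x, dtype=float) if spec.test != "chi_square" else np.asarray(x)
    y = np.asarray(y, dtype=float) if spec.test != "chi_square" else np.asarray(y)
    test = spec.test

    if test == "auto":
        if min(len(x), len(y)) < 3:
            raise ValueError("need n >= 3 per group")
        normal = all(
            sps.shapiro(v).pvalue > spec.alpha_normality for v in (x, y)
        )
        test = "two_sample_t" if normal else "mann_whitney"

    if test in ("two_sample_t", "mann_whitney", "paired_t"):
        if min(len(x), len(y)) < 3:
            raise ValueError("need n >= 3 per group")
        if np.var(x) == 0 and np.var(y) == 0:
            raise ValueError(
                f"contrast {spec.name!r}: zero variance in both groups"
            )

    if test == "two_sample_t":
        res = sps.ttest_ind(x, y)
        n = len(x) + len(y)
        direction = _direction(x, y)
    elif test == "mann_whitney":
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        n = len(x) + len(y)
        direction = _direction(x, y)
    elif test == "paired_t":
        if len(x) != len(y):
            raise ValueError("paired test requires matched vectors")
        diff = x - y
        if np.var(diff) == 0:
            raise ValueError(
                f"contrast {spec.name!r}: paired differences have zero variance"
            )
        res = sps.ttest_rel(x, y)
        n = len(x)
        direction = _direction(x, y)
    elif test == "chi_square":
        table = np.atleast_2d(x)
        res = sps.chi2_contingency(table)
        n = int(table.sum())
        direction = "n/a"
    elif test == "spearman":
        if len(x) != len(y):
            raise ValueError("spearman requires matched vectors")
        res = sps.spearmanr(x, y)
        n = len(x)
        direction = (
            "positive" if res.statistic > 0
            else ("negative" if res.statistic < 0 else "zero")
        )
    else:  # pragma: no cover
        raise ValueError(test)

    return dict(
        contrast=spec.name,
        family=spec.family,
        test=test,
        statistic=float(res.statistic),
        p_raw=float(res.pvalue),
        n=n,
        direction=direction,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced,
    capped at 1). Empty input yields an empty array."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_families(results: pd.DataFrame) -> pd.DataFrame:
    """Add a p_fdr column, adjusting within each analysis family."""
    out = results.copy()
    out["p_fdr"] = np.nan
    for _, idx in out.groupby("family").groups.items():
        out.loc[idx, "p_fdr"] = bh_fdr(out.loc[idx, "p_raw"].to_numpy())
    return out


def correlate_change(
    delta_neuro: pd.DataFrame,
    delta_behavior: pd.DataFrame,
    on: str = "subject",
    neuro_col: str = "delta",
    behavior_col: str = "delta",
    family: str = "correlations",
) -> dict:
    """Spearman correlation between per-subject neural and behavioral
    change scores (post - pre), matched on the subject column."""
    merged = delta_neuro.merge(
        delta_behavior, on=on, suffixes=("_neuro", "_behavior")
    )
    a = neuro_col + ("_neuro" if neuro_col == behavior_col else "")
    b = behavior_col + ("_behavior" if neuro_col == behavior_col else "")
    if len(merged) < 4:
        raise ValueError("need at least 4 matched subjects for correlation")
    spec = ContrastSpec(name=f"{a}~{b}", test="spearman", family=family)
    return run_contrast(spec, merged[a].to_numpy(), merged[b].to_numpy())
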