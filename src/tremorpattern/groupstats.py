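"""Per-feature two-group comparison with FDR control.

For every canonical feature the two pattern groups (A vs S) are compared
with either Welch's two-sided t-test (when both groups pass the
Shapiro–Wilk normality test at α = 0.05) or the two-sided Wilcoxon
rank-sum test (normal approximation with continuity correction).  The 63
raw p-values are then adjusted jointly with the Benjamini–Hochberg
step-up procedure, and a feature is called significant at adjusted
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .segmentio import FEATURE_NAMES

ALPHA_NORMALITY = 0.05
ALPHA_SIGNIFICANCE = 0.05


@dataclass
class ComparisonRow:
    feature: str
    mean_S: float
    sd_S: float
    mean_A: float
    sd_A: float
    test_used: str          # "t_test" or "wilcoxon"
    p_raw: float
    p_adj: float
    significant: bool
    degenerate: bool = False  # constant feature, no test possible


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _single_feature_test(a: np.ndarray, s: np.ndarray) -> tuple[str, float, bool]:
    """Choose and run the two-sample test; returns (test, p, degenerate)."""
    if np.ptp(a) == 0 and np.ptp(s) == 0:
        return "t_test", 1.0, True
    normal = True
    for g in (a, s):
        if np.ptp(g) == 0:
            normal = False
            break
        if stats.shapiro(g).pvalue < ALPHA_NORMALITY:
            normal = False
            break
    if normal:
        p = stats.ttest_ind(a, s, equal_var=False).pvalue
        return "t_test", float(p), False
    p = stats.mannwhitneyu(a, s, alternative="two-sided", method="asymptotic").pvalue
    return "wilcoxon", float(p), False


def compare_features(ft: pd.DataFrame) -> pd.DataFrame:
    """Group statistics, test choice and BH-adjusted p per feature.

    ``ft`` is a feature table with a ``label`` column containing both "A"
    and "S" (≥ 3 segments each).
    """
    for label in ("A", "S"):
        if (ft["label"] == label).sum() < 3:
            raise ValueError(f"need >= 3 segments with label {label}")
    a_rows = ft[ft["label"] == "A"]
    s_rows = ft[ft["label"] == "S"]
    rows = []
    for feature in FEATURE_NAMES:
        a = a_rows[feature].to_numpy(dtype=float)
        s = s_rows[feature].to_numpy(dtype=float)
        test, p, degenerate = _single_feature_test(a, s)
        rows.append(ComparisonRow(
            feature=feature,
            mean_S=float(np.mean(s)), sd_S=float(np.std(s, ddof=1)),
            mean_A=float(np.mean(a)), sd_A=float(np.std(a, ddof=1)),
            test_used=test, p_raw=max(p, np.nextafter(0, 1)),
            p_adj=np.nan, significant=False, degenerate=degenerate,
        ))
    p_adj = bh_adjust([r.p_raw for r in rows])
    for r, pa in zip(rows, p_adj):
        r.p_adj = float(pa)
        r.significant = bool(pa < ALPHA_SIGNIFICANCE)
    return pd.DataFrame([r.__dict__ for r in rows])


def write_comparison(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# alpha={ALPHA_SIGNIFICANCE}, m={len(df)}, "
                 "adjustment=benjamini-hochberg\n")
        df.to_csv(fh, index=False, float_format="%.6g")
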