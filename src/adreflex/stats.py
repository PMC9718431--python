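"""Statistical battery on feature windows.

Group comparisons follow the analysis plan: Welch two-sample t-tests for AD
vs non-AD feature differences, one-way ANOVA across the three stimuli, and a
single-pass >3-SD outlier rule applied per feature per group before testing.
Significance is assessed at alpha = 0.01 and no multiple-testing correction is
applied; the report records the number of tests so a reader can Bonferroni-
correct externally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sst

from .features import FIVE_FEATURES

__all__ = ["GroupComparison", "remove_outliers", "compare_ad_vs_non",
           "compare_stimuli", "stats_report"]

ALPHA = 0.01


@dataclass
class GroupComparison:
    feature: str
    comparison: str          # e.g. "ad_vs_non", "anova_stimuli", "startle_vs_none"
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    n_removed_outliers: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        return d


def remove_outliers(values: np.ndarray, z_threshold: float = 3.0, ddof: int = 1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of values more than ``z_threshold`` SDs from the mean.

    The z-scores use the group's own mean and sample SD (computed once, not
    iteratively).  Zero-variance groups are returned untouched with a warning.
    Returns (kept values, removed indices).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("outlier removal needs at least 3 values")
    sd = x.std(ddof=ddof)
    if sd == 0:
        warnings.warn("zero variance: no outliers removed")
        return x, np.empty(0, dtype=int)
    z = np.abs(x - x.mean()) / sd
    removed = np.flatnonzero(z > z_threshold)
    return np.delete(x, removed), removed


def _group_values(frame: pd.DataFrame, feature: str, label: str | list[str],
                  label_col: str = "label") -> np.ndarray:
    labels = [label] if isinstance(label, str) else label
    vals = frame.loc[frame[label_col].isin(labels) & frame["valid"], feature].to_numpy(dtype=float)
    return vals[np.isfinite(vals)]


def compare_ad_vs_non(frame: pd.DataFrame,
                      features: tuple[str, ...] = FIVE_FEATURES,
                      alpha: float = ALPHA,
                      non_ad_labels: tuple[str, ...] = ("none",)) -> list[GroupComparison]:
    """Welch t-test per feature: AD windows vs non-AD windows, after per-group
    3-SD outlier removal."""
    out = []
    for feat in features:
        a = _group_values(frame, feat, "ad")
        b = _group_values(frame, feat, list(non_ad_labels))
        if a.size < 2 or b.size < 2:
            raise ValueError(f"group too small for t-test on {feat}: {a.size} vs {b.size}")
        a_clean, ra = remove_outliers(a) if a.size >= 3 else (a, np.empty(0, int))
        b_clean, rb = remove_outliers(b) if b.size >= 3 else (b, np.empty(0, int))
        stat, p = sst.ttest_ind(a_clean, b_clean, equal_var=False)
        out.append(GroupComparison(
            feature=feat, comparison="ad_vs_non", groups=("ad",) + tuple(non_ad_labels),
            statistic=float(stat), p_value=float(p), alpha=alpha,
            significant=bool(p < alpha), n_removed_outliers=int(ra.size + rb.size)))
    return out


def compare_stimuli(frame: pd.DataFrame,
                    features: tuple[str, ...] = FIVE_FEATURES,
                    alpha: float = ALPHA,
                    stimuli: tuple[str, ...] = ("ad", "startle", "tail_pinch")
                    ) -> list[GroupComparison]:
    """One-way ANOVA per feature across the three stimuli, plus per-stimulus
    vs-baseline Welch t-tests reported alongside."""
    out = []
    for feat in features:
        groups = []
        removed = 0
        for stim in stimuli:
            g = _group_values(frame, feat, stim)
            if g.size < 2:
                raise ValueError(f"group {stim} too small for ANOVA on {feat}")
            g_clean, r = remove_outliers(g) if g.size >= 3 else (g, np.empty(0, int))
            groups.append(g_clean)
            removed += r.size
        fstat, p = sst.f_oneway(*groups)
        out.append(GroupComparison(
            feature=feat, comparison="anova_stimuli", groups=stimuli,
            statistic=float(fstat), p_value=float(p), alpha=alpha,
            significant=bool(p < alpha), n_removed_outliers=removed))

        base = _group_values(frame, feat, "none")
        base_clean, _ = remove_outliers(base) if base.size >= 3 else (base, np.empty(0, int))
        for stim, g_clean in zip(stimuli, groups):
            stat, p = sst.ttest_ind(g_clean, base_clean, equal_var=False)
            out.append(GroupComparison(
                feature=feat, comparison=f"{stim}_vs_none", groups=(stim, "none"),
                statistic=float(stat), p_value=float(p), alpha=alpha,
                significant=bool(p < alpha)))
    return out


def stats_report(frame: pd.DataFrame, alpha: float = ALPHA) -> dict:
    """Full battery as a JSON-ready dict (with the number of tests performed)."""
    comparisons = compare_ad_vs_non(frame, alpha=alpha) + compare_stimuli(frame, alpha=alpha)
    return {
        "alpha": alpha,
        "n_tests": len(comparisons),
        "comparisons": [c.to_dict() for c in comparisons],
    }
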