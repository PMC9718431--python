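"""Windowed sympathovagal features with per-trial-day min-max scaling.

Five selected features are computed on non-overlapping half-open 15-s windows
aligned to the recording start:

* ``n_bursts``   — sympathetic burst count (bursts whose start falls in the window)
* ``iskna_avg``  — mean iskNA envelope over the window (µV), sympathetic tone
* ``median_nn``  — median NN interval (ms), inversely related to heart rate
* ``rmssd``      — root mean square of successive NN differences (ms), vagal index
* ``pnn5``       — % of successive NN differences > 5 ms (rat-scale pNN50 analogue)

NN-based features use the NN intervals whose terminating beat lies in the
window; windows with fewer than three NN intervals are flagged invalid and
excluded downstream.  Normalization is min-max within each (animal, trial day)
group — matching how day-long recording sessions are scaled in practice — with
an optional train-only mode that fits the extrema on training windows alone to
avoid information leaking across the train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .processing import BeatSeries, SknaDerived
from .simulate import StimulusAnnotation

__all__ = [
    "FIVE_FEATURES",
    "FeatureVector",
    "ScalingState",
    "hrv_features",
    "window_features",
    "assign_labels",
    "fit_scaling",
    "apply_scaling",
    "invert_scaling",
    "leakage_audit",
    "select_features",
    "extended_feature_columns",
    "sympathovagal_peak_windows",
]

FIVE_FEATURES = ("n_bursts", "iskna_avg", "median_nn", "rmssd", "pnn5")
PNN_THRESHOLD_MS = 5.0
ID_COLUMNS = ("animal_id", "trial_day", "window_index", "start_s", "end_s", "valid")


@dataclass(frozen=True)
class FeatureVector:
    n_bursts: float
    iskna_avg: float
    median_nn: float
    rmssd: float
    pnn5: float
    extended: dict = field(default_factory=dict)


def hrv_features(nn_ms: np.ndarray, threshold_ms: float = PNN_THRESHOLD_MS
                 ) -> tuple[float, float, float]:
    """(medianNN, RMSSD, pnn5) of one window's NN sequence.

    RMSSD = sqrt(mean(diff(nn)^2)); pnn5 = 100 * fraction of |diff(nn)| > 5 ms.
    Requires at least two intervals (one successive difference).
    """
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 2:
        raise ValueError("need at least two NN intervals")
    d = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(d * d)))
    pnn = float(100.0 * np.mean(np.abs(d) > threshold_ms))
    return float(np.median(nn)), rmssd, pnn


def _extended_bank(nn: np.ndarray, burst_rows: list, iskna_win: np.ndarray) -> dict[str, float]:
    """Additional time-domain HRV, burst-morphology and iskNA-distribution
    features: a documented superset used to exercise feature selection, not a
    claim about any particular historical 36-feature bank."""
    out: dict[str, float] = {}
    if nn.size >= 3:
        d = np.diff(nn)
        out["mean_nn"] = float(np.mean(nn))
        out["sdnn"] = float(np.std(nn, ddof=1))
        out["cv_nn"] = out["sdnn"] / out["mean_nn"]
        out["min_nn"] = float(np.min(nn))
        out["max_nn"] = float(np.max(nn))
        out["pnn10"] = float(100.0 * np.mean(np.abs(d) > 10.0))
        out["sd_succ_diff"] = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    else:
        for k in ("mean_nn", "sdnn", "cv_nn", "min_nn", "max_nn", "pnn10", "sd_succ_diff"):
            out[k] = np.nan
    durs = [b.end_s - b.start_s for b in burst_rows]
    peaks = [b.peak_uv for b in burst_rows]
    out["burst_dur_mean"] = float(np.mean(durs)) if durs else 0.0
    out["burst_peak_mean"] = float(np.mean(peaks)) if peaks else 0.0
    out["iskna_q50"] = float(np.median(iskna_win))
    out["iskna_q90"] = float(np.quantile(iskna_win, 0.9))
    out["iskna_max"] = float(np.max(iskna_win))
    out["iskna_sd"] = float(np.std(iskna_win))
    return out


def extended_feature_columns() -> list[str]:
    return ["mean_nn", "sdnn", "cv_nn", "min_nn", "max_nn", "pnn10", "sd_succ_diff",
            "burst_dur_mean", "burst_peak_mean", "iskna_q50", "iskna_q90", "iskna_max",
            "iskna_sd"]


def window_features(beats: BeatSeries, skd: SknaDerived, duration_s: float,
                    window_s: float = 15.0, stride_s: float | None = None,
                    animal_id: str = "", trial_day: int = 0,
                    include_extended: bool = False) -> pd.DataFrame:
    """Raw feature vectors on half-open windows [t, t+window_s) from t = 0."""
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    stride = window_s if stride_s is None else stride_s
    starts = np.arange(0.0, duration_s - window_s + 1e-9, stride)

    burst_starts = np.array([b.start_s for b in skd.bursts])
    fs = skd.sampling_rate
    rows = []
    for w, t0 in enumerate(starts):
        t1 = t0 + window_s
        i0, i1 = np.searchsorted(burst_starts, [t0, t1])
        n_bursts = int(i1 - i0)
        s0, s1 = int(round(t0 * fs)), min(int(round(t1 * fs)), skd.iskna.size)
        iskna_avg = float(np.mean(skd.iskna[s0:s1]))

        j0, j1 = np.searchsorted(beats.nn_end_times, [t0, t1])
        nn = beats.nn_ms[j0:j1]
        valid = nn.size >= 3
        if valid:
            median_nn, rmssd, pnn5 = hrv_features(nn)
        else:
            median_nn = rmssd = pnn5 = np.nan
        row = {
            "animal_id": animal_id, "trial_day": trial_day, "window_index": w,
            "start_s": t0, "end_s": t1, "valid": valid,
            "n_bursts": n_bursts, "iskna_avg": iskna_avg,
            "median_nn": median_nn, "rmssd": rmssd, "pnn5": pnn5,
        }
        if include_extended:
            row.update(_extended_bank(nn, skd.bursts[i0:i1], skd.iskna[s0:s1]))
        rows.append(row)
    return pd.DataFrame(rows)


def assign_labels(frame: pd.DataFrame, annotations: list[StimulusAnnotation],
                  trial_is_ad: dict[int, bool] | None = None,
                  overlap_frac: float = 0.5,
                  ad_episode_tail_s: float = 90.0) -> pd.DataFrame:
    """Label windows by overlap with the stimulus epoch / AD episode.

    A window takes a stimulus label when at least ``overlap_frac`` of it lies
    inside the labeled interval.  For startle and tail pinch that interval is
    the stimulus epoch itself.  For CRD trials that passed the AD criteria
    (``trial_is_ad``, keyed by annotation index) the labeled interval is the
    *episode*: stimulus onset through ``ad_episode_tail_s`` past the stimulus
    end, because the AD response — elevated pressure, bradycardia and the
    vagal surge — outlasts the distension.  The default tail (90 s) is the end
    of the modeled vagal phase (onset + 30 s lag + 120 s duration).  Set
    ``ad_episode_tail_s=0`` for strict epoch-only labeling.  Failed-CRD
    windows and everything else are "none".
    """
    labels = np.array(["none"] * len(frame), dtype=object)
    t0 = frame["start_s"].to_numpy()
    t1 = frame["end_s"].to_numpy()
    width = t1 - t0
    for idx, ann in enumerate(annotations):
        if ann.kind == "crd":
            if not (trial_is_ad or {}).get(idx, False):
                continue
            end = min(ann.end_s + ad_episode_tail_s, ann.release_s)
            ov = np.minimum(t1, end) - np.maximum(t0, ann.onset_s)
            labels[ov >= overlap_frac * width] = "ad"
        elif ann.kind in ("startle", "tail_pinch"):
            ov = np.minimum(t1, ann.end_s) - np.maximum(t0, ann.onset_s)
            labels[ov >= overlap_frac * width] = ann.kind
    out = frame.copy()
    out["label"] = labels
    return out


# ---------------------------------------------------------------------------
# min-max scaling per (animal, trial day)


@dataclass
class ScalingState:
    """Observed (min, max) per (animal_id, trial_day, feature)."""

    bounds: dict[tuple[str, int, str], tuple[float, float]]
    features: tuple[str, ...]

    def key(self, animal_id: str, trial_day: int, feature: str) -> tuple[float, float]:
        k = (animal_id, int(trial_day), feature)
        if k not in self.bounds:
            raise KeyError(f"no scaling state for group {k[:2]} (feature {feature})")
        return self.bounds[k]


def fit_scaling(frame: pd.DataFrame, feature_cols: tuple[str, ...] = FIVE_FEATURES,
                fit_mask: np.ndarray | None = None) -> ScalingState:
    """Min/max per feature within each (animal, trial day) group.

    ``fit_mask`` restricts the rows the extrema are computed from (train-only
    mode); bounds are still keyed by every group present in those rows.
    """
    data = frame if fit_mask is None else frame.loc[np.asarray(fit_mask)]
    data = data[data["valid"]]
    bounds: dict[tuple[str, int, str], tuple[float, float]] = {}
    for (animal, day), grp in data.groupby(["animal_id", "trial_day"], sort=True):
        if len(grp) < 2:
            warnings.warn(f"scaling group ({animal}, day {day}) has <2 windows")
        for feat in feature_cols:
            vals = grp[feat].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            bounds[(animal, int(day), feat)] = (float(vals.min()), float(vals.max()))
    return ScalingState(bounds=bounds, features=tuple(feature_cols))


def apply_scaling(frame: pd.DataFrame, state: ScalingState, clip: bool = True) -> pd.DataFrame:
    """Add ``<feature>_norm`` columns: (x - min) / (max - min), clipped to [0, 1].

    Degenerate groups (max == min) map to 0.0 with a warning.  Groups absent
    from the state raise.
    """
    out = frame.copy()
    for feat in state.features:
        out[f"{feat}_norm"] = np.nan
    for (animal, day), grp in out.groupby(["animal_id", "trial_day"], sort=False):
        for feat in state.features:
            lo, hi = state.key(animal, int(day), feat)
            x = grp[feat].to_numpy(dtype=float)
            if hi > lo:
                scaled = (x - lo) / (hi - lo)
                if clip:
                    scaled = np.clip(scaled, 0.0, 1.0)
            else:
                warnings.warn(
                    f"feature {feat} constant in group ({animal}, day {day}); scaled to 0.0"
                )
                scaled = np.zeros_like(x)
            out.loc[grp.index, f"{feat}_norm"] = scaled
    return out


def invert_scaling(frame: pd.DataFrame, state: ScalingState) -> pd.DataFrame:
    """Recover raw values from ``<feature>_norm`` columns (inverse of apply)."""
    out = frame.copy()
    for (animal, day), grp in out.groupby(["animal_id", "trial_day"], sort=False):
        for feat in state.features:
            lo, hi = state.key(animal, int(day), feat)
            out.loc[grp.index, feat] = grp[f"{feat}_norm"].to_numpy(dtype=float) * (hi - lo) + lo
    return out


def leakage_audit(frame: pd.DataFrame, state: ScalingState,
                  mask: np.ndarray) -> dict[str, float]:
    """Fraction of ``mask`` rows whose unclipped scaled value falls outside [0, 1].

    Quantifies the information leaked by same-day scaling versus train-only
    scaling: with extrema fit on training windows only, test windows can
    exceed the [0, 1] range before clipping.
    """
    sub = frame.loc[np.asarray(mask)]
    report: dict[str, float] = {}
    for feat in state.features:
        n_out = 0
        n_tot = 0
        for (animal, day), grp in sub.groupby(["animal_id", "trial_day"], sort=False):
            lo, hi = state.key(animal, int(day), feat)
            x = grp[feat].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            n_tot += x.size
            if hi > lo:
                s = (x - lo) / (hi - lo)
                n_out += int(np.sum((s < 0) | (s > 1)))
        report[feat] = n_out / n_tot if n_tot else 0.0
    return report


def sympathovagal_peak_windows(frame: pd.DataFrame) -> tuple[int, int]:
    """Window indices of peak sympathetic and peak vagal activity.

    The sympathetic score is the sum of min-max-normalized ``n_bursts`` and
    ``iskna_avg``; the vagal score sums normalized ``rmssd`` and ``pnn5``.
    In the AD cascade the sympathetic peak precedes the vagal one.
    """
    sub = frame[frame["valid"]]

    def score(cols: tuple[str, str]) -> pd.Series:
        total = None
        for c in cols:
            x = sub[c].to_numpy(dtype=float)
            rng_ = x.max() - x.min()
            s = (x - x.min()) / rng_ if rng_ > 0 else np.zeros_like(x)
            total = s if total is None else total + s
        return pd.Series(total, index=sub.index)

    symp = score(("n_bursts", "iskna_avg"))
    vagal = score(("rmssd", "pnn5"))
    return int(sub.loc[symp.idxmax(), "window_index"]), int(sub.loc[vagal.idxmax(), "window_index"])


def select_features(frame: pd.DataFrame, feature_cols: list[str],
                    label_col: str = "label", k: int = 5,
                    n_bins: int = 4) -> list[tuple[str, float, float]]:
    """Rank features by chi-squared association between quartile bins and class.

    Each feature is discretized into quartile bins; the chi-squared statistic
    of the bin × class contingency table ranks the features.  Returns the top
    ``k`` as (feature, statistic, p-value), highest statistic first.
    """
    labels = frame[label_col].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("feature selection needs at least two classes")
    if len(feature_cols) < k:
        warnings.warn(f"only {len(feature_cols)} features available; returning all")
    ranked = []
    for feat in feature_cols:
        x = frame[feat].to_numpy(dtype=float)
        ok = np.isfinite(x)
        xv, yv = x[ok], labels[ok]
        edges = np.unique(np.quantile(xv, np.linspace(0, 1, n_bins + 1)))
        if edges.size < 2:  # constant feature: no association
            ranked.append((feat, 0.0, 1.0))
            continue
        bins = np.clip(np.searchsorted(edges, xv, side="right") - 1, 0, edges.size - 2)
        table = pd.crosstab(bins, yv).to_numpy()
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if min(table.shape) < 2:
            ranked.append((feat, 0.0, 1.0))
            continue
        stat, p, _, _ = chi2_contingency(table, correction=False)
        ranked.append((feat, float(stat), float(p)))
    ranked.sort(key=lambda r: r[1], reverse=True)
    return ranked[: max(k, 0)] if len(feature_cols) >= k else ranked
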