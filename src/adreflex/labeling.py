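"""Clinical ground-truth labeling of CRD trials as autonomic dysreflexia.

A CRD trial counts as AD when the tail-cuff systolic pressure rises by at
least 15 mmHg and mean arterial pressure by at least 10 mmHg over the
pre-stimulus baseline (thresholds inclusive), with auxiliary checks that the
pressure rise was preceded by sympathetic bursts and followed by bradycardia.
"Rapid" is operationalized as the pressure peak occurring within the stimulus
minute plus a 120-s grace period; the baseline reference is the mean of the
cuff samples in the 120 s before onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .processing import BeatSeries, SknaDerived
from .simulate import Recording, StimulusAnnotation

__all__ = ["ADCriteria", "ADEventLabel", "label_trial", "label_recording", "cohort_ad_rate"]


@dataclass(frozen=True)
class ADCriteria:
    """Thresholds and auxiliary requirements for calling a CRD trial AD."""

    sbp_delta_min: float = 15.0       # mmHg, inclusive
    map_delta_min: float = 10.0       # mmHg, inclusive
    require_bradycardia: bool = True
    require_preceding_sympathetic: bool = True
    baseline_window_s: float = 120.0  # pre-onset reference window
    peak_window_extra_s: float = 120.0  # grace period after stimulus end for the BP peak
    vagal_window_s: tuple[float, float] = (30.0, 180.0)  # rel. onset, for the bradycardia check
    map_mode: str = "conjunctive"     # "conjunctive" | "audit" (MAP reported but not required)

    def __post_init__(self) -> None:
        if self.sbp_delta_min <= 0 or self.map_delta_min <= 0:
            raise ValueError("pressure thresholds must be positive")
        if self.map_mode not in ("conjunctive", "audit"):
            raise ValueError("map_mode must be 'conjunctive' or 'audit'")


@dataclass
class ADEventLabel:
    """Full criteria breakdown for one CRD trial (auditable, not just the verdict)."""

    trial_id: str
    is_ad: bool
    delta_sbp: float
    delta_map: float
    bradycardia_observed: bool
    sympathetic_precedes: bool
    sbp_peak_time_s: float
    baseline_sbp: float
    baseline_map: float
    details: dict = field(default_factory=dict)


def _bp_arrays(recording: Recording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bp = recording.channel("bp")
    interval = 1.0 / recording.channel_specs["bp"].sampling_rate
    t = np.arange(bp.shape[0]) * interval
    sbp = bp[:, 0]
    dbp = bp[:, 1]
    mapv = dbp + (sbp - dbp) / 3.0
    return t, sbp, mapv


def label_trial(recording: Recording, annotation: StimulusAnnotation,
                skd: SknaDerived | None, beats: BeatSeries | None,
                criteria: ADCriteria = ADCriteria()) -> ADEventLabel:
    """Apply the AD criteria to one CRD trial.

    Requires at least two cuff samples in both the baseline window and the
    stimulus epoch (the 30-s cuff cadence makes shorter windows unusable).
    ``skd``/``beats`` may be None only when the corresponding auxiliary
    requirement is disabled.
    """
    if annotation.kind != "crd":
        raise ValueError(f"label_trial applies to CRD trials, got kind {annotation.kind!r}")
    t, sbp, mapv = _bp_arrays(recording)
    onset, end = annotation.onset_s, annotation.end_s

    base_mask = (t >= onset - criteria.baseline_window_s) & (t < onset)
    stim_mask = (t >= onset) & (t <= end)
    if base_mask.sum() < 2 or stim_mask.sum() < 2:
        raise ValueError(
            "insufficient BP samples for labeling: the 30-s cuff cadence needs "
            f">=2 samples in both baseline ({int(base_mask.sum())}) and stimulus "
            f"({int(stim_mask.sum())}) windows"
        )
    peak_mask = (t >= onset) & (t <= end + criteria.peak_window_extra_s)

    base_sbp = float(np.mean(sbp[base_mask]))
    base_map = float(np.mean(mapv[base_mask]))
    k_peak = int(np.argmax(sbp[peak_mask]))
    peak_time = float(t[peak_mask][k_peak])
    delta_sbp = float(sbp[peak_mask].max() - base_sbp)
    delta_map = float(mapv[peak_mask].max() - base_map)

    brady = False
    if beats is not None and beats.nn_ms.size:
        hr = 60_000.0 / beats.nn_ms
        tt = beats.nn_end_times
        base_hr = hr[(tt >= onset - criteria.baseline_window_s) & (tt < onset)]
        lo, hi = criteria.vagal_window_s
        vagal_hr = hr[(tt >= onset + lo) & (tt < onset + hi)]
        if base_hr.size >= 2 and vagal_hr.size >= 2:
            se = base_hr.std(ddof=1) / np.sqrt(base_hr.size)
            brady = bool(vagal_hr.mean() < base_hr.mean() - 2.0 * se)
    elif criteria.require_bradycardia:
        raise ValueError("bradycardia check requires a BeatSeries")

    symp = False
    if skd is not None:
        symp = any(onset <= b.start_s <= peak_time for b in skd.bursts)
    elif criteria.require_preceding_sympathetic:
        raise ValueError("sympathetic-precedence check requires SknaDerived bursts")

    is_ad = delta_sbp >= criteria.sbp_delta_min
    if criteria.map_mode == "conjunctive":
        is_ad = is_ad and delta_map >= criteria.map_delta_min
    if criteria.require_bradycardia:
        is_ad = is_ad and brady
    if criteria.require_preceding_sympathetic:
        is_ad = is_ad and symp

    return ADEventLabel(
        trial_id=f"{recording.recording_id}_t{annotation.onset_s:.0f}",
        is_ad=bool(is_ad),
        delta_sbp=delta_sbp,
        delta_map=delta_map,
        bradycardia_observed=brady,
        sympathetic_precedes=symp,
        sbp_peak_time_s=peak_time,
        baseline_sbp=base_sbp,
        baseline_map=base_map,
        details={
            "sbp_crossed": delta_sbp >= criteria.sbp_delta_min,
            "map_crossed": delta_map >= criteria.map_delta_min,
            "map_mode": criteria.map_mode,
        },
    )


def label_recording(recording: Recording, skd: SknaDerived, beats: BeatSeries,
                    criteria: ADCriteria = ADCriteria()) -> dict[int, ADEventLabel]:
    """Label every CRD annotation of a recording; keyed by annotation index."""
    out: dict[int, ADEventLabel] = {}
    for idx, ann in enumerate(recording.annotations):
        if ann.kind == "crd":
            out[idx] = label_trial(recording, ann, skd, beats, criteria)
    return out


def cohort_ad_rate(labels: list[ADEventLabel]) -> tuple[float, tuple[float, float]]:
    """Fraction of AD-positive CRD trials with a Wilson 95% binomial CI."""
    if not labels:
        raise ValueError("cohort_ad_rate requires at least one label")
    n_pos = sum(lab.is_ad for lab in labels)
    n = len(labels)
    lo, hi = proportion_confint(n_pos, n, alpha=0.05, method="wilson")
    return n_pos / n, (float(lo), float(hi))
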