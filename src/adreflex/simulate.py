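"""Synthetic multi-channel rat recordings with a programmable sympathovagal cascade.

Generates labeled ECG, skin-nerve-activity (skNA), tail-cuff blood-pressure and
skin-temperature channels for four stimulus classes: colorectal distension
(CRD, the autonomic-dysreflexia trigger), acoustic startle, tail pinch, and
no-stimulus baseline.  The construction mirrors what the downstream analysis
assumes about each class:

* CRD that successfully triggers autonomic dysreflexia (AD) produces a burst
  of sympathetic skNA activity at stimulus onset, a lagged vagal surge
  (lengthened, more variable NN intervals, i.e. bradycardia with elevated
  RMSSD/pnn5), and a systolic blood-pressure ramp of ~+20 mmHg.
* "Failed" CRD trials keep the sympathetic surge but attenuate the pressure
  ramp below the AD thresholds and damp the vagal response.
* Acoustic startle raises the skNA burst rate and heart rate (shortened NN).
* Tail pinch doubles skNA burst amplitude without changing the burst rate and
  inhibits vagal variability.

Every injected event is recorded in a ground-truth structure so detectors and
classifiers can be scored against construction rather than against themselves.
All randomness flows from ``SimulationConfig.seed`` through purpose-split
`numpy` generators, so a fixed config reproduces recordings bit for bit.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ChannelSpec",
    "StimulusAnnotation",
    "SimulationConfig",
    "TrialTruth",
    "Recording",
    "default_channel_specs",
    "simulate_recording",
    "simulate_cohort",
    "iter_cohort",
    "build_schedule",
]

STIMULUS_KINDS = ("crd", "startle", "tail_pinch", "none")
CLASS_LABELS = ("ad", "startle", "tail_pinch", "none")


@dataclass(frozen=True)
class ChannelSpec:
    """Name, sampling rate (Hz) and units of one recorded channel."""

    name: str
    sampling_rate: float
    units: str

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")


def default_channel_specs(config: "SimulationConfig | None" = None) -> dict[str, ChannelSpec]:
    cfg = config or SimulationConfig()
    return {
        "ecg": ChannelSpec("ecg", cfg.fs_ecg, "mV"),
        "skna": ChannelSpec("skna", cfg.fs_skna, "uV"),
        "bp": ChannelSpec("bp", 1.0 / cfg.bp_interval_s, "mmHg"),
        "temperature": ChannelSpec("temperature", cfg.fs_temperature, "degC"),
    }


@dataclass(frozen=True)
class StimulusAnnotation:
    """One 1-min stimulus epoch plus its recovery period."""

    kind: str
    onset_s: float
    duration_s: float = 60.0
    recovery_s: float = 600.0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; expected one of {STIMULUS_KINDS}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.recovery_s < 0:
            raise ValueError(f"recovery_s must be >= 0, got {self.recovery_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    @property
    def release_s(self) -> float:
        """End of the recovery period."""
        return self.end_s + self.recovery_s


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the experimental protocol (channel rates, trial days,
    three CRD distensions per day with 10-min recoveries, ~70% CRD-to-AD
    conversion) and, where the protocol gives only effect directions, values
    a physiologist would call realistic for an awake restrained rat.
    """

    seed: int = 0
    n_animals: int = 4
    trial_days: tuple[int, ...] = (7, 9, 11, 14)

    # heart rate / NN-interval process
    baseline_hr_bpm: tuple[float, float] = (400.0, 20.0)  # mean, sd across animals
    rr_jitter_ms: float = 2.0           # white beat-to-beat variability
    rr_slow_sd_ms: float = 3.0          # AR(1) slow component, stationary sd
    rr_slow_phi: float = 0.95

    # sympathetic skNA bursts
    burst_rate_base: float = 2.0        # bursts/min at rest
    burst_rate_ad: float = 20.0         # extra bursts/min over the CRD stimulus minute
    burst_rate_startle: float = 15.0
    iskna_gain_tailpinch: float = 2.0   # burst-amplitude multiplier; rate unchanged
    burst_amp_uv: float = 4.0
    burst_duration_range_s: tuple[float, float] = (0.1, 1.0)
    burst_decay_tau_s: float = 30.0     # surge rate decays from onset with this constant
    burst_min_gap_s: float = 0.15

    # vagal phase (AD signature: lagged parasympathetic surge)
    vagal_lag_s: float = 30.0           # delay from sympathetic-surge onset to vagal onset
    vagal_peak_offset_s: float = 60.0   # vagal peak at onset + lag + offset
    vagal_width_s: float = 30.0         # Gaussian width of the vagal bump
    vagal_duration_s: float = 120.0
    ad_bradycardia_frac: float = 0.15   # fractional NN lengthening at vagal peak
    vagal_jitter_gain_ad: float = 3.0   # beat-to-beat jitter multiplier at vagal peak
    vagal_jitter_gain_startle: float = 2.0
    vagal_jitter_gain_tailpinch: float = 0.5  # vagal inhibition
    failed_crd_vagal_scale: float = 0.3

    startle_tachycardia_frac: float = 0.10
    stimulus_taper_tau_s: float = 15.0  # decay of startle/pinch modulation after stimulus end

    # blood pressure (tail cuff)
    baseline_sbp_mmhg: float = 120.0
    baseline_dbp_mmhg: float = 90.0
    sbp_delta: Mapping[str, float] = field(
        default_factory=lambda: {"ad": 20.0, "startle": 7.0, "tail_pinch": 5.0, "none": 0.0}
    )
    dbp_delta: Mapping[str, float] = field(
        default_factory=lambda: {"ad": 14.0, "startle": 1.0, "tail_pinch": 0.4, "none": 0.0}
    )
    bp_noise_sd: float = 1.5
    bp_decay_tau_s: float = 120.0
    bp_delta_jitter_sd: float = 2.0
    ad_success_prob: float = 0.7
    failed_crd_attenuation: tuple[float, float] = (0.2, 0.75)  # uniform range, × threshold ramp

    # waveform rendering
    noise_sd_ecg: float = 0.05          # mV
    noise_sd_skna: float = 1.0          # µV (broadband, before nerve-band filtering)
    qrs_amp_mv: float = 1.0
    fs_ecg: float = 10_000.0
    fs_skna: float = 10_000.0
    fs_temperature: float = 2.0
    bp_interval_s: float = 30.0
    baseline_temp_c: float = 34.0

    # cohort schedule
    baseline_s: float = 60.0            # quiet segment before the first trial
    n_crd_per_day: int = 3
    stimulus_duration_s: float = 60.0
    recovery_s: float = 600.0
    startle_day_prob: float = 0.75      # probability a trial day includes a startle trial
    tailpinch_day_prob: float = 0.75

    def __post_init__(self) -> None:
        for name in ("burst_rate_base", "burst_rate_ad", "burst_rate_startle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ad_success_prob <= 1.0:
            raise ValueError("ad_success_prob must be in [0, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        lo, hi = self.failed_crd_attenuation
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("failed_crd_attenuation must satisfy 0 <= lo <= hi < 1")

    def channel_specs(self) -> dict[str, ChannelSpec]:
        return default_channel_specs(self)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sbp_delta"] = dict(self.sbp_delta)
        d["dbp_delta"] = dict(self.dbp_delta)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("trial_days", "baseline_hr_bpm", "burst_duration_range_s", "failed_crd_attenuation"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrialTruth:
    """Ground truth for one stimulus trial, as injected by the simulator."""

    kind: str
    onset_s: float
    duration_s: float
    recovery_s: float
    is_ad: bool
    class_label: str              # ad / startle / tail_pinch / none (failed CRD -> none)
    delta_sbp: float
    delta_dbp: float
    delta_map: float
    sympathetic_onset_s: float | None
    vagal_onset_s: float | None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Recording:
    """Multi-channel recording plus stimulus annotations and generator truth."""

    animal_id: str
    trial_day: int
    duration_s: float
    channel_specs: dict[str, ChannelSpec]
    channels: dict[str, np.ndarray]
    annotations: list[StimulusAnnotation]
    truth: dict
    config: SimulationConfig | None = None

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels or self.channels[name] is None:
            raise KeyError(f"channel {name!r} not present in recording {self.recording_id}")
        return self.channels[name]

    @property
    def recording_id(self) -> str:
        return f"{self.animal_id}_day{self.trial_day:02d}"

    def bp_frame(self):
        """Blood pressure as (time_s, sbp, dbp, map) columns."""
        import pandas as pd

        bp = self.channel("bp")
        t = np.arange(bp.shape[0]) * (1.0 / self.channel_specs["bp"].sampling_rate)
        sbp, dbp = bp[:, 0], bp[:, 1]
        return pd.DataFrame(
            {"time_s": t, "sbp": sbp, "dbp": dbp, "map": dbp + (sbp - dbp) / 3.0}
        )


# ---------------------------------------------------------------------------
# internal helpers


def _stable_int(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _rng(config: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed)] + [int(k) % (2**32) for k in key])


def _validate_schedule(schedule: Sequence[StimulusAnnotation], duration_s: float | None = None) -> None:
    ordered = sorted(schedule, key=lambda a: a.onset_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.onset_s < prev.release_s:
            raise ValueError(
                f"overlapping stimulus annotations: {prev.kind} at {prev.onset_s:.1f}s "
                f"(busy until {prev.release_s:.1f}s incl. recovery) overlaps "
                f"{nxt.kind} at {nxt.onset_s:.1f}s"
            )
    if duration_s is not None:
        for ann in ordered:
            if ann.end_s > duration_s:
                raise ValueError(
                    f"stimulus {ann.kind} at {ann.onset_s:.1f}s extends past recording end {duration_s:.1f}s"
                )


def _plan_trials(config: SimulationConfig, schedule: Sequence[StimulusAnnotation],
                 rng: np.random.Generator) -> list[TrialTruth]:
    trials: list[TrialTruth] = []
    for ann in sorted(schedule, key=lambda a: a.onset_s):
        jitter = rng.normal(0.0, config.bp_delta_jitter_sd)
        if ann.kind == "crd":
            success = rng.random() < config.ad_success_prob
            if success:
                dsbp = config.sbp_delta["ad"] + jitter
                ddbp = config.dbp_delta["ad"] + 0.5 * jitter
                label = "ad"
            else:
                # attenuate the ramp below the SBP threshold, keep the surge
                frac = rng.uniform(*config.failed_crd_attenuation)
                dsbp = 15.0 * frac
                ddbp = (15.0 * frac) * config.dbp_delta["ad"] / config.sbp_delta["ad"]
                label = "none"
            trials.append(TrialTruth(
                kind="crd", onset_s=ann.onset_s, duration_s=ann.duration_s,
                recovery_s=ann.recovery_s, is_ad=success, class_label=label,
                delta_sbp=dsbp, delta_dbp=ddbp, delta_map=ddbp + (dsbp - ddbp) / 3.0,
                sympathetic_onset_s=ann.onset_s,
                vagal_onset_s=ann.onset_s + config.vagal_lag_s,
            ))
        elif ann.kind in ("startle", "tail_pinch"):
            dsbp = config.sbp_delta[ann.kind] + 0.5 * jitter
            ddbp = config.dbp_delta[ann.kind] + 0.25 * jitter
            trials.append(TrialTruth(
                kind=ann.kind, onset_s=ann.onset_s, duration_s=ann.duration_s,
                recovery_s=ann.recovery_s, is_ad=False, class_label=ann.kind,
                delta_sbp=dsbp, delta_dbp=ddbp, delta_map=ddbp + (dsbp - ddbp) / 3.0,
                sympathetic_onset_s=ann.onset_s if ann.kind == "startle" else None,
                vagal_onset_s=None,
            ))
        else:  # "none": an annotated quiet epoch, no injected effect
            trials.append(TrialTruth(
                kind="none", onset_s=ann.onset_s, duration_s=ann.duration_s,
                recovery_s=ann.recovery_s, is_ad=False, class_label="none",
                delta_sbp=0.0, delta_dbp=0.0, delta_map=0.0,
                sympathetic_onset_s=None, vagal_onset_s=None,
            ))
    return trials


def _vagal_bump(t: np.ndarray, trial: TrialTruth, config: SimulationConfig) -> np.ndarray:
    """Gaussian vagal-surge envelope in [0, 1]; nonzero only within the vagal phase."""
    if trial.vagal_onset_s is None:
        return np.zeros_like(t)
    start = trial.vagal_onset_s
    stop = start + config.vagal_duration_s
    peak = trial.onset_s + config.vagal_lag_s + config.vagal_peak_offset_s
    bump = np.exp(-0.5 * ((t - peak) / config.vagal_width_s) ** 2)
    bump[(t < start) | (t > stop)] = 0.0
    return bump


def _epoch_envelope(t: np.ndarray, trial: TrialTruth, config: SimulationConfig) -> np.ndarray:
    """1 during the stimulus epoch, exponential taper afterwards."""
    env = np.zeros_like(t)
    inside = (t >= trial.onset_s) & (t < trial.onset_s + trial.duration_s)
    env[inside] = 1.0
    after = t >= trial.onset_s + trial.duration_s
    env[after] = np.exp(-(t[after] - (trial.onset_s + trial.duration_s)) / config.stimulus_taper_tau_s)
    return env


def _nn_modulation(t: np.ndarray, trials: Sequence[TrialTruth], config: SimulationConfig
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Return (mean-NN multiplier, beat-to-beat jitter gain) at times ``t``."""
    mean_mult = np.ones_like(t)
    jitter_gain = np.ones_like(t)
    for trial in trials:
        if trial.kind == "crd":
            scale = 1.0 if trial.is_ad else config.failed_crd_vagal_scale
            bump = _vagal_bump(t, trial, config)
            mean_mult *= 1.0 + config.ad_bradycardia_frac * scale * bump
            jitter_gain *= 1.0 + (config.vagal_jitter_gain_ad - 1.0) * scale * bump
        elif trial.kind == "startle":
            env = _epoch_envelope(t, trial, config)
            mean_mult *= 1.0 - config.startle_tachycardia_frac * env
            jitter_gain *= 1.0 + (config.vagal_jitter_gain_startle - 1.0) * env
        elif trial.kind == "tail_pinch":
            env = _epoch_envelope(t, trial, config)
            jitter_gain *= 1.0 + (config.vagal_jitter_gain_tailpinch - 1.0) * env
    return mean_mult, jitter_gain


def _simulate_beats(config: SimulationConfig, animal_id: str, duration_s: float,
                    trials: Sequence[TrialTruth], rng: np.random.Generator) -> np.ndarray:
    """Beat times (s) from an AR(1)+white NN-interval process with phase modulation.

    Modulation depends on absolute time, which depends on the beats themselves;
    a short fixed-point iteration (vectorized) resolves the circularity.
    """
    rng_animal = _rng(config, _stable_int(animal_id), 0xA11)
    hr = rng_animal.normal(*config.baseline_hr_bpm)
    hr = float(np.clip(hr, 150.0, 800.0))
    mu0 = 60_000.0 / hr  # ms

    min_mult = 1.0 - config.startle_tachycardia_frac
    n_max = int(math.ceil(duration_s * 1000.0 / (mu0 * min_mult) * 1.05)) + 16

    slow_innov = rng.normal(0.0, config.rr_slow_sd_ms * math.sqrt(1 - config.rr_slow_phi**2), n_max)
    white = rng.normal(0.0, config.rr_jitter_ms, n_max)
    from scipy.signal import lfilter

    slow = lfilter([1.0], [1.0, -config.rr_slow_phi], slow_innov)

    nn = mu0 + slow + white
    nn = np.maximum(nn, 0.3 * mu0)
    t = np.cumsum(nn) / 1000.0
    for _ in range(3):
        t_prev = np.concatenate(([0.0], t[:-1]))
        mean_mult, jitter_gain = _nn_modulation(t_prev, trials, config)
        nn = mu0 * mean_mult + slow + jitter_gain * white
        nn = np.maximum(nn, 0.3 * mu0)
        t = np.cumsum(nn) / 1000.0
    beats = t[t < duration_s - 0.05]
    return beats


def _burst_rate(t: np.ndarray, trials: Sequence[TrialTruth], config: SimulationConfig) -> np.ndarray:
    """Instantaneous burst rate (per second) at times ``t``."""
    rate = np.full_like(t, config.burst_rate_base / 60.0)
    tau = config.burst_decay_tau_s
    for trial in trials:
        if trial.kind == "crd":
            extra = config.burst_rate_ad
        elif trial.kind == "startle":
            extra = config.burst_rate_startle
        else:
            continue
        # normalize the decaying profile so the expected extra count over the
        # stimulus minute equals the configured bursts/min
        dur = trial.duration_s
        c = dur / (tau * (1.0 - math.exp(-dur / tau)))
        mask = t >= trial.onset_s
        rate[mask] += (extra / 60.0) * c * np.exp(-(t[mask] - trial.onset_s) / tau)
    return rate


def _peak_burst_rate(trials: Sequence[TrialTruth], config: SimulationConfig) -> float:
    peak = config.burst_rate_base / 60.0
    tau = config.burst_decay_tau_s
    for trial in trials:
        if trial.kind == "crd":
            extra = config.burst_rate_ad
        elif trial.kind == "startle":
            extra = config.burst_rate_startle
        else:
            continue
        c = trial.duration_s / (tau * (1.0 - math.exp(-trial.duration_s / tau)))
        peak = max(peak, config.burst_rate_base / 60.0 + (extra / 60.0) * c)
    return peak


def _simulate_bursts(config: SimulationConfig, duration_s: float,
                     trials: Sequence[TrialTruth], rng: np.random.Generator
                     ) -> list[tuple[float, float, float]]:
    """(start_s, end_s, amplitude_uv) burst packets from a thinned Poisson process."""
    lam_max = _peak_burst_rate(trials, config)
    n_cand = rng.poisson(lam_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
    accept_u = rng.uniform(0.0, 1.0, n_cand)
    durations = rng.uniform(*config.burst_duration_range_s, n_cand)
    amps = config.burst_amp_uv * rng.lognormal(0.0, 0.3, n_cand)
    keep = accept_u < _burst_rate(cand, trials, config) / lam_max

    bursts: list[tuple[float, float, float]] = []
    prev_end = -math.inf
    for start, dur, amp in zip(cand[keep], durations[keep], amps[keep]):
        if start < prev_end + config.burst_min_gap_s:
            continue
        end = min(start + dur, duration_s - 1e-4)
        if end - start < config.burst_duration_range_s[0]:
            continue
        for trial in trials:
            if trial.kind == "tail_pinch" and trial.onset_s <= start < trial.onset_s + trial.duration_s:
                amp *= config.iskna_gain_tailpinch
        bursts.append((float(start), float(end), float(amp)))
        prev_end = end
    return bursts


def _qrs_template(fs: float, amp: float) -> tuple[np.ndarray, int]:
    """Template rat QRS-T complex; returns (waveform, index of the R peak)."""
    half = int(round(0.08 * fs))
    t = (np.arange(-half, half + 1) / fs) * 1000.0  # ms
    w = (
        amp * np.exp(-0.5 * (t / 2.5) ** 2)
        - 0.15 * amp * np.exp(-0.5 * ((t + 7.0) / 2.0) ** 2)
        - 0.25 * amp * np.exp(-0.5 * ((t - 7.0) / 2.0) ** 2)
        + 0.12 * amp * np.exp(-0.5 * ((t - 45.0) / 12.0) ** 2)
    )
    return w.astype(np.float32), half


def _render_ecg(config: SimulationConfig, duration_s: float, beats: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    fs = config.fs_ecg
    n = int(round(duration_s * fs))
    ecg = rng.standard_normal(n, dtype=np.float32)
    ecg *= np.float32(config.noise_sd_ecg)
    template, r_off = _qrs_template(fs, config.qrs_amp_mv)
    width = template.size
    idx = np.round(beats * fs).astype(np.int64)
    for i in idx:
        lo = i - r_off
        hi = lo + width
        if lo < 0 or hi > n:
            a = max(lo, 0)
            b = min(hi, n)
            ecg[a:b] += template[a - lo : b - lo]
        else:
            ecg[lo:hi] += template
    return ecg


def _render_skna(config: SimulationConfig, duration_s: float,
                 bursts: Sequence[tuple[float, float, float]],
                 rng: np.random.Generator) -> np.ndarray:
    fs = config.fs_skna
    n = int(round(duration_s * fs))
    skna = rng.standard_normal(n, dtype=np.float32)
    skna *= np.float32(config.noise_sd_skna)
    for start, end, amp in bursts:
        i0 = int(round(start * fs))
        i1 = min(int(round(end * fs)), n)
        m = i1 - i0
        if m < 8:
            continue
        tau = np.arange(m, dtype=np.float32) / np.float32(fs)
        f1 = rng.uniform(550.0, 750.0)
        f2 = rng.uniform(750.0, 950.0)
        ph1, ph2 = rng.uniform(0.0, 2 * math.pi, 2)
        carrier = np.sin(2 * math.pi * f1 * tau + ph1) + 0.6 * np.sin(2 * math.pi * f2 * tau + ph2)
        env = np.hanning(m).astype(np.float32)
        skna[i0:i1] += np.float32(amp * 0.8) * env * carrier.astype(np.float32)
    return skna


def _render_bp(config: SimulationConfig, duration_s: float,
               trials: Sequence[TrialTruth], rng: np.random.Generator) -> np.ndarray:
    t = np.arange(0.0, duration_s, config.bp_interval_s)
    sbp = np.full(t.size, config.baseline_sbp_mmhg)
    dbp = np.full(t.size, config.baseline_dbp_mmhg)
    for trial in trials:
        shape = np.zeros(t.size)
        ramp = (t >= trial.onset_s) & (t <= trial.onset_s + trial.duration_s)
        shape[ramp] = (t[ramp] - trial.onset_s) / trial.duration_s
        after = t > trial.onset_s + trial.duration_s
        shape[after] = np.exp(-(t[after] - (trial.onset_s + trial.duration_s)) / config.bp_decay_tau_s)
        sbp += trial.delta_sbp * shape
        dbp += trial.delta_dbp * shape
    sbp = sbp + rng.normal(0.0, config.bp_noise_sd, t.size)
    dbp = dbp + rng.normal(0.0, 0.8 * config.bp_noise_sd, t.size)
    return np.column_stack([sbp, dbp])


def _render_temperature(config: SimulationConfig, duration_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    n = int(round(duration_s * config.fs_temperature))
    innov = rng.normal(0.0, 0.02, n)
    drift = lfilter([1.0], [1.0, -0.995], innov)
    return (config.baseline_temp_c + drift).astype(np.float64)


# ---------------------------------------------------------------------------
# public operations


def simulate_recording(config: SimulationConfig, animal_id: str, trial_day: int,
                       schedule: Sequence[StimulusAnnotation],
                       duration_s: float | None = None,
                       render: bool = True) -> Recording:
    """Simulate one multi-channel recording for the given stimulus schedule.

    Parameters
    ----------
    duration_s
        Recording length; defaults to the end of the last recovery period
        (or ``config.baseline_s`` for an empty schedule).
    render
        When False, skip waveform synthesis and return truth only (the
        channels map is empty).  Truth is bit-identical either way.
    """
    schedule = list(schedule)
    _validate_schedule(schedule)
    if duration_s is None:
        duration_s = max([a.release_s for a in schedule], default=config.baseline_s)
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    _validate_schedule(schedule, duration_s)

    day_key = (_stable_int(animal_id), int(trial_day))
    rng_plan = _rng(config, *day_key, 1)
    rng_beats = _rng(config, *day_key, 2)
    rng_bursts = _rng(config, *day_key, 3)
    rng_noise = _rng(config, *day_key, 4)
    rng_bp = _rng(config, *day_key, 5)

    trials = _plan_trials(config, schedule, rng_plan)
    beats = _simulate_beats(config, animal_id, duration_s, trials, rng_beats)
    bursts = _simulate_bursts(config, duration_s, trials, rng_bursts)

    truth = {
        "beat_times_s": beats,
        "nn_ms": np.diff(beats) * 1000.0,
        "bursts": bursts,
        "trials": [tr.to_dict() for tr in trials],
    }

    channels: dict[str, np.ndarray] = {}
    if render:
        channels["ecg"] = _render_ecg(config, duration_s, beats, rng_noise)
        channels["skna"] = _render_skna(config, duration_s, bursts, rng_noise)
        channels["bp"] = _render_bp(config, duration_s, trials, rng_bp)
        channels["temperature"] = _render_temperature(config, duration_s, rng_bp)

    return Recording(
        animal_id=animal_id,
        trial_day=int(trial_day),
        duration_s=float(duration_s),
        channel_specs=config.channel_specs(),
        channels=channels,
        annotations=sorted(schedule, key=lambda a: a.onset_s),
        truth=truth,
        config=config,
    )


def build_schedule(config: SimulationConfig, animal_id: str, trial_day: int
                   ) -> list[StimulusAnnotation]:
    """Randomized trial order for one animal-day: three CRDs plus, on randomly
    chosen days, one startle and/or one tail-pinch trial."""
    rng = _rng(config, _stable_int(animal_id), int(trial_day), 0x5C)
    kinds = ["crd"] * config.n_crd_per_day
    if rng.random() < config.startle_day_prob:
        kinds.append("startle")
    if rng.random() < config.tailpinch_day_prob:
        kinds.append("tail_pinch")
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]
    schedule = []
    t = config.baseline_s
    for kind in kinds:
        schedule.append(StimulusAnnotation(kind=kind, onset_s=t,
                                           duration_s=config.stimulus_duration_s,
                                           recovery_s=config.recovery_s))
        t += config.stimulus_duration_s + config.recovery_s
    return schedule


def iter_cohort(config: SimulationConfig, render: bool = True) -> Iterator[Recording]:
    """Stream one recording per animal × trial day (memory-friendly)."""
    for i in range(1, config.n_animals + 1):
        animal_id = f"rat{i:02d}"
        for day in config.trial_days:
            schedule = build_schedule(config, animal_id, day)
            yield simulate_recording(config, animal_id, day, schedule, render=render)


def simulate_cohort(config: SimulationConfig, render: bool = True) -> list[Recording]:
    """Materialized cohort; prefer :func:`iter_cohort` for large configs."""
    return list(iter_cohort(config, render=render))
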