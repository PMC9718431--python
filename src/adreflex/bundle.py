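"""Recording-bundle I/O: one CSV per channel plus a JSON metadata sidecar.

Layout of a bundle directory (one per recording)::

    <bundle>/
        ecg.csv           time_s,value        (mV, 10 kHz)
        skna.csv          time_s,value        (µV, 10 kHz)
        bp.csv            time_s,sbp,dbp      (mmHg, one row per cuff reading)
        temperature.csv   time_s,value        (°C, 2 Hz)
        meta.json         channel specs, annotations, generator truth, config hash

Floats are printed with enough digits that float32 waveform samples round-trip
exactly.  The blood-pressure channel carries systolic and diastolic columns
(MAP is derived as dbp + (sbp - dbp)/3 downstream).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ChannelSpec, Recording, SimulationConfig, StimulusAnnotation

__all__ = ["config_hash", "sha256_file", "write_recording", "read_recording",
           "write_cohort", "iter_bundles"]

_FLOAT_FMT = "%.10g"


def config_hash(obj) -> str:
    """sha256 of the canonical JSON form of a config-like object."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()


def sha256_file(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_channel_csv(path: Path, t: np.ndarray, values: np.ndarray, header: str) -> None:
    data = np.column_stack([t] + ([values] if values.ndim == 1 else [values[:, i] for i in range(values.shape[1])]))
    np.savetxt(path, data, delimiter=",", fmt=_FLOAT_FMT, header=header, comments="")


def write_recording(recording: Recording, out_dir: Path | str) -> Path:
    """Write a recording bundle; returns the bundle directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in recording.channels.items():
        spec = recording.channel_specs[name]
        t = np.arange(arr.shape[0]) / spec.sampling_rate
        header = "time_s,sbp,dbp" if name == "bp" else "time_s,value"
        _write_channel_csv(out / f"{name}.csv", t, np.asarray(arr), header)

    truth = {
        "beat_times_s": np.asarray(recording.truth["beat_times_s"]).tolist(),
        "bursts": [list(b) for b in recording.truth["bursts"]],
        "trials": recording.truth["trials"],
    }
    meta = {
        "animal_id": recording.animal_id,
        "trial_day": recording.trial_day,
        "duration_s": recording.duration_s,
        "channel_specs": {k: {"name": v.name, "sampling_rate": v.sampling_rate, "units": v.units}
                          for k, v in recording.channel_specs.items()},
        "annotations": [{"kind": a.kind, "onset_s": a.onset_s, "duration_s": a.duration_s,
                         "recovery_s": a.recovery_s} for a in recording.annotations],
        "truth": truth,
        "config": recording.config.to_dict() if recording.config else None,
        "config_hash": config_hash(recording.config) if recording.config else None,
    }
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1)
    return out


def _read_channel_csv(path: Path) -> np.ndarray:
    try:
        frame = pd.read_csv(path, dtype=float)
    except Exception as err:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"corrupt channel file {path}: {err}") from err
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax()) + 2  # 1-based incl. header
        raise ValueError(f"corrupt channel file {path}: non-numeric value near line {row}")
    return frame


def read_recording(bundle_dir: Path | str) -> Recording:
    """Read a bundle written by :func:`write_recording`."""
    d = Path(bundle_dir)
    with open(d / "meta.json") as fh:
        meta = json.load(fh)
    specs = {k: ChannelSpec(**v) for k, v in meta["channel_specs"].items()}
    channels: dict[str, np.ndarray] = {}
    for name in specs:
        path = d / f"{name}.csv"
        if not path.exists():
            continue
        frame = _read_channel_csv(path)
        if name == "bp":
            channels[name] = frame[["sbp", "dbp"]].to_numpy()
        else:
            dtype = np.float32 if name in ("ecg", "skna") else np.float64
            channels[name] = frame["value"].to_numpy(dtype=dtype)
    truth = dict(meta["truth"])
    truth["beat_times_s"] = np.asarray(truth["beat_times_s"], dtype=float)
    truth["nn_ms"] = np.diff(truth["beat_times_s"]) * 1000.0
    truth["bursts"] = [tuple(b) for b in truth["bursts"]]
    config = SimulationConfig.from_dict(meta["config"]) if meta.get("config") else None
    return Recording(
        animal_id=meta["animal_id"],
        trial_day=int(meta["trial_day"]),
        duration_s=float(meta["duration_s"]),
        channel_specs=specs,
        channels=channels,
        annotations=[StimulusAnnotation(**a) for a in meta["annotations"]],
        truth=truth,
        config=config,
    )


def write_cohort(recordings, out_dir: Path | str) -> list[Path]:
    out = Path(out_dir)
    paths = []
    for rec in recordings:
        paths.append(write_recording(rec, out / rec.recording_id))
    return paths


def iter_bundles(root: Path | str):
    """Yield recordings from every bundle directory under ``root``."""
    root = Path(root)
    for meta in sorted(root.glob("*/meta.json")):
        yield read_recording(meta.parent)
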