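"""End-to-end orchestration: simulate → condition → label → features → model → stats.

Every run is driven by a single :class:`PipelineConfig` (JSON-serializable)
and one global seed; per-stage seeds are derived from it, so any artifact can
be regenerated from config + seed alone.  Recordings are streamed one at a
time (a full day-long 10 kHz recording is processed and reduced to its window
features before the next is synthesized), keeping memory flat in cohort size.

The manifest lists every written artifact with its sha256, the config hash and
per-stage timings; fixed-seed reruns produce byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, features as feat, labeling, processing, stats as statsmod
from .bundle import config_hash, sha256_file, write_recording
from .classify import TrainConfig
from .labeling import ADCriteria
from .simulate import SimulationConfig, iter_cohort

__all__ = ["PipelineConfig", "assemble_dataset", "prepare_model_matrix", "run_pipeline"]

log = logging.getLogger("adreflex")

_FLOAT_FMT = "%.10g"

# Event neighborhood: windows from 1 min before stimulus onset to 2.5 min after
# stimulus end.  Informative data points cluster around events (tens of windows
# per event, spanning the episode and its surroundings), so the modeling set is
# built from these neighborhoods first and padded with quiet windows; the
# non-stimulus class then contains the transition windows (vagal tails,
# decaying surges) that make it the genuinely confusable class.
NEIGHBORHOOD_PRE_S = 60.0
NEIGHBORHOOD_POST_S = 150.0


@dataclass(frozen=True)
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    criteria: ADCriteria = field(default_factory=ADCriteria)
    train: TrainConfig = field(default_factory=TrainConfig)
    window_s: float = 15.0
    include_extended: bool = False
    scaling_mode: str = "same-day"        # "same-day" (protocol) | "train-only" (no leakage)
    binary_scope: str = "all"             # negatives: "all" windows | "crd-only" trial windows
    n_windows_target: int | None = 2200   # subsample the modeling set to this many windows
    alpha: float = 0.01
    seed: int = 0
    write_recordings: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scaling_mode not in ("same-day", "train-only"):
            raise ValueError("scaling_mode must be 'same-day' or 'train-only'")
        if self.binary_scope not in ("all", "crd-only"):
            raise ValueError("binary_scope must be 'all' or 'crd-only'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "criteria" in d:
            c = dict(d["criteria"])
            if "vagal_window_s" in c:
                c["vagal_window_s"] = tuple(c["vagal_window_s"])
            d["criteria"] = ADCriteria(**c)
        if "train" in d:
            t = dict(d["train"])
            if "hidden_layers" in t:
                t["hidden_layers"] = tuple(t["hidden_layers"])
            d["train"] = TrainConfig(**t)
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


def _stage(name: str, timings: dict):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, timings[name])
    return _Timer()


def assemble_dataset(config: PipelineConfig, out_dir: Path | None = None
                     ) -> tuple[pd.DataFrame, list[labeling.ADEventLabel]]:
    """Simulate the cohort and reduce it to labeled feature windows.

    Returns the concatenated window frame (raw features + class label) and the
    per-CRD-trial AD labels.  Window class labels use the computed AD labels,
    not the generator truth, so the pipeline is end-to-end honest.
    """
    sim = replace(config.simulation, seed=config.seed)
    frames: list[pd.DataFrame] = []
    trial_labels: list[labeling.ADEventLabel] = []
    truth_flags: list[bool] = []
    for rec in iter_cohort(sim):
        beats, skd = processing.process_recording(rec)
        rec_labels = labeling.label_recording(rec, skd, beats, config.criteria)
        crd_idx = [i for i, a in enumerate(rec.annotations) if a.kind == "crd"]
        for i in crd_idx:
            trial_labels.append(rec_labels[i])
            truth_flags.append(bool(rec.truth["trials"][i]["is_ad"]))
        frame = feat.window_features(
            beats, skd, rec.duration_s, window_s=config.window_s,
            animal_id=rec.animal_id, trial_day=rec.trial_day,
            include_extended=config.include_extended)
        frame = feat.assign_labels(frame, rec.annotations,
                                   {i: rec_labels[i].is_ad for i in crd_idx})
        kinds = np.array(["none"] * len(frame), dtype=object)
        near = np.zeros(len(frame), dtype=bool)
        t0 = frame["start_s"].to_numpy()
        t1 = frame["end_s"].to_numpy()
        for ann in rec.annotations:
            ov = np.minimum(t1, ann.end_s) - np.maximum(t0, ann.onset_s)
            kinds[ov >= 0.5 * (t1 - t0)] = ann.kind
            near |= (t0 >= ann.onset_s - NEIGHBORHOOD_PRE_S) & (
                t0 < ann.end_s + NEIGHBORHOOD_POST_S)
        frame["stimulus_kind"] = kinds  # raw epoch kind, independent of AD verdict
        frame["near_event"] = near      # within the event neighborhood (see prepare_model_matrix)
        frames.append(frame)
        if out_dir is not None and config.write_recordings:
            write_recording(rec, Path(out_dir) / "recordings" / rec.recording_id)
        del rec, beats, skd
    full = pd.concat(frames, ignore_index=True)
    full.attrs["truth_is_ad"] = truth_flags
    return full, trial_labels


def prepare_model_matrix(frame: pd.DataFrame, config: PipelineConfig
                         ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Select valid windows, subsample to the target count, normalize.

    Returns (modeling frame with ``<feat>_norm`` columns, X matrix, multiclass
    label vector).  Normalization is per-(animal, trial day) min-max; in
    train-only mode the caller re-fits scaling after splitting.
    """
    cols = list(feat.FIVE_FEATURES)
    ok = frame["valid"] & np.isfinite(frame[cols].to_numpy(dtype=float)).all(axis=1)
    sub = frame.loc[ok].reset_index(drop=True)
    target = config.n_windows_target
    if target is not None and len(sub) > target:
        # event-centered composition: keep every window near a stimulus event,
        # pad with (seeded) quiet windows up to the target count
        rng = np.random.default_rng(config.seed + 2)
        near = sub["near_event"].to_numpy() if "near_event" in sub else np.zeros(len(sub), bool)
        near_idx = np.flatnonzero(near)
        quiet_idx = np.flatnonzero(~near)
        if near_idx.size >= target:
            keep = rng.choice(near_idx, size=target, replace=False)
        else:
            pad = rng.choice(quiet_idx, size=target - near_idx.size, replace=False)
            keep = np.concatenate([near_idx, pad])
        sub = sub.iloc[np.sort(keep)].reset_index(drop=True)
    state = feat.fit_scaling(sub, tuple(cols))
    sub = feat.apply_scaling(sub, state)
    X = sub[[f"{c}_norm" for c in cols]].to_numpy(dtype=float)
    y = sub["label"].to_numpy()
    return sub, X, y


def _binary_labels(sub: pd.DataFrame, scope: str) -> tuple[np.ndarray, np.ndarray]:
    """(y, row mask) for the AD-vs-non-AD task."""
    y = np.where(sub["label"].to_numpy() == "ad", "ad", "non_ad")
    if scope == "crd-only":
        mask = (sub["stimulus_kind"].to_numpy() == "crd")
    else:
        mask = np.ones(len(sub), dtype=bool)
    return y, mask


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=float)


def run_pipeline(config: PipelineConfig, out_dir: Path | str) -> dict:
    """Execute every stage and return (and write) the artifact manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings: dict[str, float] = {}
    notes: list[str] = []
    artifacts: dict[str, str] = {}

    with _stage("simulate+process+features", timings):
        frame, trial_labels = assemble_dataset(config, out_dir=out)

    with _stage("label-report", timings):
        rate, ci = labeling.cohort_ad_rate(trial_labels)
        lab_frame = pd.DataFrame([{
            "trial_id": lab.trial_id, "is_ad": lab.is_ad,
            "delta_sbp": lab.delta_sbp, "delta_map": lab.delta_map,
            "bradycardia_observed": lab.bradycardia_observed,
            "sympathetic_precedes": lab.sympathetic_precedes,
        } for lab in trial_labels])
        lab_frame.to_csv(out / "labels.csv", index=False, float_format=_FLOAT_FMT)
        _write_json(out / "ad_rate.json",
                    {"ad_rate": rate, "ci95": list(ci), "n_trials": len(trial_labels)})

    with _stage("normalize", timings):
        sub, X, y_multi = prepare_model_matrix(frame, config)
        sub.to_csv(out / "features.csv", index=False, float_format=_FLOAT_FMT)

    with _stage("stats", timings):
        try:
            _write_json(out / "stats.json", statsmod.stats_report(sub, alpha=config.alpha))
        except ValueError as err:
            notes.append(f"stats skipped: {err}")

    # binary AD-vs-non-AD task
    with _stage("train-binary", timings):
        y_bin, mask = _binary_labels(sub, config.binary_scope)
        yb = y_bin[mask]
        Xb = X[mask]
        if (yb == "ad").sum() >= 3 and (yb == "non_ad").sum() >= 3:
            tcfg = replace(config.train, task="binary", seed=config.seed + 1)
            tr, va, te = classify.split_stratified(yb, tcfg)
            if config.scaling_mode == "train-only":
                sel = sub.loc[mask].reset_index(drop=True)
                tr_mask = np.zeros(len(sel), dtype=bool)
                tr_mask[tr] = True
                state = feat.fit_scaling(sel, tuple(feat.FIVE_FEATURES), fit_mask=tr_mask)
                scaled = feat.apply_scaling(sel, state)
                Xb = scaled[[f"{c}_norm" for c in feat.FIVE_FEATURES]].to_numpy(dtype=float)
                te_mask = np.zeros(len(sel), dtype=bool)
                te_mask[te] = True
                _write_json(out / "scaling_audit.json",
                            feat.leakage_audit(sel, state, te_mask))
            model = classify.train_model(Xb[tr], yb[tr], Xb[va], yb[va], tcfg,
                                         feature_names=list(feat.FIVE_FEATURES))
            report = classify.evaluate(model, Xb[te], yb[te])
            (out / "model_binary.json").write_text(model.to_json())
            _write_json(out / "eval_binary.json", report.to_dict())
        else:
            notes.append("binary task skipped: fewer than 3 windows in a class")

    with _stage("crossval-multiclass", timings):
        counts = pd.Series(y_multi).value_counts()
        folds = int(min(config.train.cv_folds, counts.min()))
        if len(counts) >= 2 and folds >= 2:
            if folds < config.train.cv_folds:
                notes.append(f"multiclass cv_folds reduced to {folds} (smallest class has {counts.min()})")
            mcfg = replace(config.train, task="multiclass", cv_folds=folds, seed=config.seed + 1)
            cv = classify.cross_validate(X, y_multi, mcfg)
            _write_json(out / "cv_multiclass.json", {
                "cv_mean": cv["cv_mean"], "cv_sd": cv["cv_sd"],
                "fold_accuracies": cv["fold_accuracies"],
                "confusion": cv["confusion"].tolist(), "labels": cv["labels"],
                "most_confused": classify.most_confused_class(cv["confusion"], cv["labels"]),
            })
        else:
            notes.append("multiclass CV skipped: need >=2 classes with >=2 windows each")

    with _stage("manifest", timings):
        for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
            if p.name == "manifest.json":
                continue
            artifacts[p.name] = sha256_file(p)
        manifest = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "artifacts": artifacts,
            "notes": notes,
            "n_windows": int(len(sub)),
            "n_trials": len(trial_labels),
        }
        _write_json(out / "manifest.json", manifest)
        manifest["timings_s"] = timings  # timings vary run to run; kept out of the file
    return manifest
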