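"""Shared fixtures.

The expensive fixtures are session-scoped: one fully rendered CRD trial for
the signal-processing/labeling tests, and the full default cohort (reduced to
the 2200-window modeling set) shared by the classifier, stats and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adreflex.classify import TrainConfig, split_stratified, train_model, evaluate
from adreflex.features import FIVE_FEATURES
from adreflex.pipeline import PipelineConfig, assemble_dataset, prepare_model_matrix
from adreflex.processing import process_recording
from adreflex.simulate import SimulationConfig, StimulusAnnotation, simulate_recording

COHORT_SEED = 1


@pytest.fixture(scope="session")
def crd_recording():
    """One rendered CRD trial (60 s baseline, 60 s stimulus, 120 s recovery)."""
    cfg = SimulationConfig(seed=1)
    schedule = [StimulusAnnotation("crd", 60.0, 60.0, 120.0)]
    return simulate_recording(cfg, "rat01", 7, schedule)


@pytest.fixture(scope="session")
def crd_processed(crd_recording):
    return process_recording(crd_recording)


@pytest.fixture(scope="session")
def quiet_recording():
    """Stimulus-free recording (600 s) at default noise for detector scoring."""
    cfg = SimulationConfig(seed=2)
    return simulate_recording(cfg, "rat09", 7, [], duration_s=600.0)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort reduced to the 2200-window modeling set.

    Returns a dict with the full window frame, per-trial AD labels, the
    normalized modeling frame, feature matrix and label vectors.
    """
    config = PipelineConfig(seed=COHORT_SEED)
    frame, trial_labels = assemble_dataset(config)
    sub, X, y_multi = prepare_model_matrix(frame, config)
    y_bin = np.where(y_multi == "ad", "ad", "non_ad")
    return {
        "config": config,
        "frame": frame,
        "trial_labels": trial_labels,
        "sub": sub,
        "X": X,
        "y_multi": y_multi,
        "y_bin": y_bin,
    }


@pytest.fixture(scope="session")
def binary_eval(cohort):
    """Binary AD-vs-non-AD model trained with the 70/15/15 protocol."""
    cfg = TrainConfig(task="binary", seed=COHORT_SEED + 1)
    y = cohort["y_bin"]
    X = cohort["X"]
    tr, va, te = split_stratified(y, cfg)
    model = train_model(X[tr], y[tr], X[va], y[va], cfg, feature_names=list(FIVE_FEATURES))
    report = evaluate(model, X[te], y[te])
    return {"model": model, "report": report, "splits": (tr, va, te)}
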