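"""Windowed feature extraction, min-max scaling and chi-squared selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adreflex.features import (FIVE_FEATURES, apply_scaling, assign_labels,
                               fit_scaling, hrv_features, invert_scaling,
                               leakage_audit, select_features,
                               sympathovagal_peak_windows, window_features)
from adreflex.simulate import StimulusAnnotation


def brute_force_hrv(nn, thr=5.0):
    """Independent oracle: direct formulas on plain Python lists."""
    import math

    nn = list(map(float, nn))
    s = sorted(nn)
    m = len(s)
    median = s[m // 2] if m % 2 else 0.5 * (s[m // 2 - 1] + s[m // 2])
    diffs = [b - a for a, b in zip(nn, nn[1:])]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn = 100.0 * sum(1 for d in diffs if abs(d) > thr) / len(diffs)
    return median, rmssd, pnn


class TestHrvFeatures:
    def test_constant_sequence(self):
        med, rmssd, pnn = hrv_features([150.0, 150.0, 150.0])
        assert (med, rmssd, pnn) == (150.0, 0.0, 0.0)

    def test_hand_computed_alternating(self):
        med, rmssd, pnn = hrv_features([150.0, 160.0, 150.0])
        assert med == 150.0
        assert rmssd == pytest.approx(10.0)
        assert pnn == 100.0  # both |diffs| = 10 > 5 ms

    def test_subthreshold_differences_do_not_count(self):
        _, _, pnn = hrv_features([150.0, 154.0, 150.0])
        assert pnn == 0.0  # both |diffs| = 4 <= 5 ms

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            nn = rng.uniform(100, 250, rng.integers(2, 80))
            got = hrv_features(nn)
            want = brute_force_hrv(nn)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-9, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(50, 500), min_size=2, max_size=50),
           st.floats(-20, 20))
    def test_shift_invariance_and_bounds(self, nn, shift):
        med1, rmssd1, pnn1 = hrv_features(nn)
        med2, rmssd2, pnn2 = hrv_features([x + shift for x in nn])
        assert rmssd2 == pytest.approx(rmssd1, rel=1e-9, abs=1e-9)
        assert pnn2 == pytest.approx(pnn1, abs=1e-9)
        assert med2 == pytest.approx(med1 + shift, rel=1e-9)
        assert 0.0 <= pnn1 <= 100.0 and rmssd1 >= 0.0


class TestWindowFeatures:
    def test_window_geometry_and_validity(self, crd_processed, crd_recording):
        beats, skd = crd_processed
        frame = window_features(beats, skd, crd_recording.duration_s)
        assert len(frame) == int(crd_recording.duration_s // 15)
        assert np.allclose(frame["end_s"] - frame["start_s"], 15.0)
        assert frame["valid"].all()
        assert (frame["n_bursts"] >= 0).all()
        assert frame["pnn5"].between(0, 100).all()

    def test_burst_partition_property(self, crd_processed, crd_recording):
        beats, skd = crd_processed
        frame = window_features(beats, skd, crd_recording.duration_s)
        covered_end = frame["end_s"].max()
        total = sum(1 for b in skd.bursts if b.start_s < covered_end)
        assert frame["n_bursts"].sum() == total

    def test_sparse_beats_flagged_invalid(self, crd_processed, crd_recording):
        beats, skd = crd_processed
        import copy

        sparse = copy.copy(beats)
        keep = slice(0, 4)  # 4 beats -> 3 NN intervals, all in one window
        sparse.nn_ms = beats.nn_ms[keep]
        sparse.nn_end_times = beats.nn_end_times[keep]
        frame = window_features(sparse, skd, crd_recording.duration_s)
        assert not frame["valid"].iloc[1:].any()

    def test_sympathovagal_peak_ordering_on_ad_trial(self, crd_processed, crd_recording):
        beats, skd = crd_processed
        frame = window_features(beats, skd, crd_recording.duration_s)
        symp, vagal = sympathovagal_peak_windows(frame)
        assert symp < vagal


class TestLabeling:
    def _frame(self, n=10):
        return pd.DataFrame({
            "animal_id": "r", "trial_day": 7, "window_index": range(n),
            "start_s": np.arange(n) * 15.0, "end_s": (np.arange(n) + 1) * 15.0,
            "valid": True,
        })

    def test_epoch_only_overlap_rule_and_ad_gate(self):
        frame = self._frame()
        anns = [StimulusAnnotation("crd", 30.0, 60.0, 60.0)]
        lab_pass = assign_labels(frame, anns, {0: True}, ad_episode_tail_s=0.0)["label"]
        lab_fail = assign_labels(frame, anns, {0: False}, ad_episode_tail_s=0.0)["label"]
        assert list(lab_pass[2:6]) == ["ad"] * 4
        assert lab_pass[0] == "none" and lab_pass[6] == "none"
        assert list(lab_fail) == ["none"] * 10

    def test_ad_episode_label_extends_past_epoch(self):
        frame = self._frame(14)
        # epoch [30, 90); the default 90-s tail labels the episode [30, 180)
        anns = [StimulusAnnotation("crd", 30.0, 60.0, 150.0)]
        lab = assign_labels(frame, anns, {0: True})["label"]
        assert list(lab[2:12]) == ["ad"] * 10
        assert lab[1] == "none" and lab[12] == "none"
        # failed trial: everything stays none, surge windows included
        lab_fail = assign_labels(frame, anns, {0: False})["label"]
        assert list(lab_fail) == ["none"] * 14

    def test_ad_episode_tail_capped_at_recovery_end(self):
        frame = self._frame(14)
        # epoch [30, 90) with only 30 s recovery: episode capped at 120
        anns = [StimulusAnnotation("crd", 30.0, 60.0, 30.0)]
        lab = assign_labels(frame, anns, {0: True})["label"]
        assert list(lab[2:8]) == ["ad"] * 6
        assert lab[8] == "none"

    def test_half_overlap_boundary(self):
        frame = self._frame()
        # epoch covers [37.5, 97.5): windows 3..5 fully inside, windows 2 and 6
        # overlap exactly 50% and the rule is inclusive
        anns = [StimulusAnnotation("startle", 37.5, 60.0, 60.0)]
        lab = assign_labels(frame, anns)["label"]
        assert list(lab[2:7]) == ["startle"] * 5
        assert lab[1] == "none" and lab[7] == "none"


class TestScaling:
    def _frame(self):
        return pd.DataFrame({
            "animal_id": ["a"] * 3 + ["b"] * 3,
            "trial_day": 7,
            "window_index": range(6),
            "valid": True,
            "n_bursts": [2.0, 4.0, 6.0, 3.0, 3.0, 3.0],
            "iskna_avg": [0.1, 0.2, 0.4, 0.3, 0.5, 0.7],
            "median_nn": [140, 150, 160, 150, 155, 165],
            "rmssd": [2.0, 3.0, 4.0, 2.0, 8.0, 4.0],
            "pnn5": [0.0, 50.0, 100.0, 10.0, 20.0, 30.0],
        })

    def test_midpoint_scales_to_half(self):
        frame = self._frame()
        state = fit_scaling(frame)
        scaled = apply_scaling(frame, state)
        assert scaled.loc[1, "n_bursts_norm"] == pytest.approx(0.5)
        grp = scaled[scaled["animal_id"] == "a"]
        for feat in FIVE_FEATURES:
            assert grp[f"{feat}_norm"].min() == 0.0
            assert grp[f"{feat}_norm"].max() == 1.0

    def test_constant_feature_maps_to_zero_with_warning(self):
        frame = self._frame()
        state = fit_scaling(frame)
        with pytest.warns(UserWarning, match="constant"):
            scaled = apply_scaling(frame, state)
        assert (scaled.loc[frame["animal_id"] == "b", "n_bursts_norm"] == 0.0).all()

    def test_invert_round_trip(self):
        frame = self._frame().iloc[:3]  # avoid the degenerate group
        state = fit_scaling(frame)
        scaled = apply_scaling(frame, state)
        back = invert_scaling(scaled, state)
        for feat in FIVE_FEATURES:
            assert np.allclose(back[feat], frame[feat], atol=1e-9)

    def test_unseen_group_errors(self):
        frame = self._frame()
        state = fit_scaling(frame.iloc[:3])
        with pytest.raises(KeyError, match="scaling state"):
            apply_scaling(frame, state)

    def test_train_only_mode_leaks_nothing_but_overflows(self):
        rng = np.random.default_rng(3)
        n = 40
        frame = pd.DataFrame({
            "animal_id": "a", "trial_day": 7, "window_index": range(n), "valid": True,
            **{f: rng.normal(0, 1, n) for f in FIVE_FEATURES},
        })
        train_mask = np.zeros(n, dtype=bool)
        train_mask[:20] = True
        state = fit_scaling(frame, fit_mask=train_mask)
        audit = leakage_audit(frame, state, ~train_mask)
        assert set(audit) == set(FIVE_FEATURES)
        assert all(0.0 <= v <= 1.0 for v in audit.values())
        assert sum(audit.values()) > 0  # some test values exceed the train extrema
        # same-day fit has nothing out of range by construction
        full_state = fit_scaling(frame)
        audit_full = leakage_audit(frame, full_state, np.ones(n, dtype=bool))
        assert all(v == 0.0 for v in audit_full.values())


class TestSelectFeatures:
    def test_uninformative_feature_ranks_last(self):
        rng = np.random.default_rng(0)
        n = 80
        frame = pd.DataFrame({
            "label": ["ad"] * 40 + ["none"] * 40,
            "good": np.r_[rng.normal(5, 1, 40), rng.normal(0, 1, 40)],
            "flat": np.ones(n),
        })
        ranked = select_features(frame, ["good", "flat"], k=2)
        assert [r[0] for r in ranked] == ["good", "flat"]
        assert ranked[1][1] == 0.0

    def test_perfect_separation_statistic_equals_n(self):
        frame = pd.DataFrame({
            "label": ["ad"] * 20 + ["none"] * 20,
            "x": np.r_[np.linspace(10, 11, 20), np.linspace(0, 1, 20)],
        })
        ranked = select_features(frame, ["x"], k=1)
        assert ranked[0][1] == pytest.approx(40.0)

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"label": ["ad"] * 10, "x": np.arange(10.0)})
        with pytest.raises(ValueError, match="two classes"):
            select_features(frame, ["x"])

    def test_fewer_features_than_k_warns_and_returns_all(self):
        frame = pd.DataFrame({
            "label": ["ad"] * 10 + ["none"] * 10,
            "x": np.r_[np.ones(10), np.zeros(10)],
        })
        with pytest.warns(UserWarning, match="available"):
            ranked = select_features(frame, ["x"], k=5)
        assert len(ranked) == 1
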