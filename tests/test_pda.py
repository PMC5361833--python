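"""Pulse decomposition: beat detection, features, calibration, conversion."""

import numpy as np
import pandas as pd
import pytest

from cnibp import pda
from cnibp.pda import (CalibrationState, ConversionSlopes, calibrate,
                       convert_to_bp, decompose_beat, detect_beats,
                       extract_features, recalibration_trigger)
from cnibp.simulate import (ArtifactSpec, ChannelConfig, ComponentPulseSpec,
                            DynamicsConfig, generate_bp_trajectory,
                            synthesize_beat, synthesize_recording)

CLEAN = ChannelConfig(catheter_filter="identity", noise=False)


def _flat_recording(duration, hr, seed=0):
    dyn = DynamicsConfig(mode="flat", hr0_bpm=hr)
    traj = generate_bp_trajectory(duration, dyn, seed=seed)
    return synthesize_recording(traj, channel_config=CLEAN, seed=seed)


class TestDetectBeats:
    @pytest.mark.parametrize("hr,expected", [(60, 30), (90, 45)])
    def test_beat_count_tracks_heart_rate(self, hr, expected):
        rec = _flat_recording(30, hr)
        beats = detect_beats(rec.cuff, rec.rate_hz)
        # final incomplete cycle is dropped, hence the -1
        assert abs(len(beats) - (expected - 1)) <= 1

    def test_intervals_match_heart_rate(self):
        rec = _flat_recording(60, 75)
        beats = detect_beats(rec.cuff, rec.rate_hz)
        periods = np.diff([b.onset_s for b in beats])
        assert np.all(np.abs(periods - 60.0 / 75.0) / (60.0 / 75.0) < 0.05)

    def test_no_beats_inside_motion_burst(self):
        traj = generate_bp_trajectory(60, "flat", seed=3)
        art = ArtifactSpec("motion", 25, 35, magnitude=2.0)
        rec = synthesize_recording(traj, artifacts=[art], seed=3)
        beats = detect_beats(rec.cuff, rec.rate_hz)
        t = np.array([b.onset_s for b in beats])
        assert not np.any((t > 26) & (t < 34))
        assert len(beats) > 20  # still found outside the burst

    def test_flat_channel_rejected(self):
        with pytest.raises(ValueError):
            detect_beats(np.zeros(30000), 500.0)


class TestDecomposeBeat:
    def test_t13_recovery(self, induction_recording):
        """Noise-free simulator beats: T13 recovered within +-4 ms."""
        rec = induction_recording
        feats = extract_features(rec.cuff, rec.rate_hz)
        v = feats[feats["valid"]]
        assert len(v) > 0.9 * len(feats)
        truth = rec.beat_truth
        t13_true = np.interp(v["onset_s"], truth["onset_s"], truth["t13_true"])
        assert np.abs(v["t13_s"] - t13_true).max() < 0.004

    def test_p2p1_recovery(self, induction_recording):
        """Noise-free simulator beats: P2/P1 recovered within +-0.03."""
        rec = induction_recording
        feats = extract_features(rec.cuff, rec.rate_hz)
        v = feats[feats["valid"]]
        truth = rec.beat_truth
        p2p1_true = np.interp(v["onset_s"], truth["onset_s"], truth["p2p1_true"])
        assert np.abs(v["p2p1"] - p2p1_true).max() < 0.03

    @staticmethod
    def _foot_to_foot_beat(amps, taus, widths, period=0.9, foot_s=0.16):
        """One beat sampled foot-to-foot, P1 centred foot_s after onset."""
        t = np.arange(0, period, 1 / 500.0)
        return sum(a * np.exp(-0.5 * ((t - foot_s - tau) / w) ** 2)
                   for a, tau, w in zip(amps, taus, widths))

    def test_known_half_ratio_beat(self):
        seg = self._foot_to_foot_beat((40.0, 20.0, 12.0), (0.0, 0.14, 0.40),
                                      (0.05, 0.06, 0.05))
        f = decompose_beat(seg, 500.0, period_s=0.9)
        assert f.valid
        assert 0.396 <= f.t13_s <= 0.404
        assert 0.47 <= f.p2p1 <= 0.53

    def test_no_reflections_flagged_invalid(self):
        seg = self._foot_to_foot_beat((40.0, 0.0, 0.0), (0.0, 0.10, 0.25),
                                      (0.05, 0.06, 0.05))
        f = decompose_beat(seg, 500.0, period_s=0.9)
        assert not f.valid

    def test_scale_invariance(self, flat_recording):
        """Features are amplitude ratios and delays: multiplying the cuff
        channel by any positive gain leaves them unchanged."""
        rec = flat_recording
        a = extract_features(rec.cuff, rec.rate_hz)
        b = extract_features(3.7 * rec.cuff, rec.rate_hz)
        va, vb = a[a["valid"]], b[b["valid"]]
        assert len(va) == len(vb)
        assert np.allclose(va["t13_s"], vb["t13_s"], atol=1e-9)
        assert np.allclose(va["p2p1"], vb["p2p1"], rtol=1e-6)


@pytest.fixture(scope="module")
def flat_features(flat_recording):
    return pda.extract_features(flat_recording.cuff, flat_recording.rate_hz)


class TestCalibration:
    def test_baseline_maps_exactly_to_reference(self, flat_features):
        cal = calibrate(flat_features, 120.0, 80.0)
        base = pd.DataFrame([{
            "onset_s": 0.0, "t13_s": cal.t13_baseline_s,
            "p2p1": cal.p2p1_baseline, "valid": True}])
        out = convert_to_bp(base, cal)
        assert out["sbp"].iloc[0] == pytest.approx(120.0)
        assert out["dbp"].iloc[0] == pytest.approx(80.0)
        assert out["map"].iloc[0] == pytest.approx(80 + 40 / 3)

    def test_offsets_shift_with_reference(self, flat_features):
        a = calibrate(flat_features, 120.0, 80.0)
        b = calibrate(flat_features, 135.0, 85.0)
        assert b.sbp_offset_mmhg - a.sbp_offset_mmhg == pytest.approx(15.0)
        assert b.pp_offset_mmhg - a.pp_offset_mmhg == pytest.approx(10.0)

    def test_too_few_beats_rejected(self, flat_features):
        with pytest.raises(ValueError):
            calibrate(flat_features.iloc[:2], 120.0, 80.0)

    def test_unphysiological_reference_rejected(self, flat_features):
        with pytest.raises(ValueError):
            calibrate(flat_features, 80.0, 120.0)


def _cal(slopes=None):
    return CalibrationState(
        sbp_ref_mmhg=120.0, dbp_ref_mmhg=80.0, t13_baseline_s=0.40,
        p2p1_baseline=0.40, hr_baseline_bpm=60.0, stiffness_baseline=0.40,
        slopes=slopes or ConversionSlopes())


def _feat(t13, p2p1, hr=60.0, onset=0.0):
    return {"onset_s": onset, "t13_s": t13, "p2p1": p2p1, "hr_bpm": hr,
            "stiffness": p2p1, "valid": True}


class TestConversion:
    def test_hand_computed_systolic_shift(self):
        """T13 down 12 ms at slope -1000 mmHg/s raises SBP by 12 mmHg."""
        cal = _cal(ConversionSlopes(sbp_per_t13_mmhg_per_s=-1000.0))
        out = convert_to_bp(pd.DataFrame([_feat(0.40 - 0.012, 0.40)]), cal)
        assert out["sbp"].iloc[0] == pytest.approx(132.0)

    def test_unchanged_features_unchanged_pp(self):
        cal = _cal()
        out = convert_to_bp(pd.DataFrame([_feat(0.40, 0.40)]), cal)
        assert out["sbp"].iloc[0] - out["dbp"].iloc[0] == pytest.approx(40.0)

    def test_invalid_beats_dropped(self):
        cal = _cal()
        df = pd.DataFrame([_feat(0.40, 0.40), dict(_feat(0.40, 0.40), valid=False)])
        assert len(convert_to_bp(df, cal)) == 1

    def test_clamping_flagged(self):
        cal = _cal(ConversionSlopes(sbp_per_t13_mmhg_per_s=-10000.0))
        out = convert_to_bp(pd.DataFrame([_feat(0.37, 0.40)]), cal)
        assert bool(out["clamped"].iloc[0])
        assert out["sbp"].iloc[0] <= 300.0


class TestRecalibrationTrigger:
    def _window(self, hr, stiffness=0.40, n=30):
        return pd.DataFrame([_feat(0.40, stiffness, hr=hr, onset=i)
                             for i in range(n)])

    def test_heart_rate_exceeding_30pct_triggers(self):
        fire, reason = recalibration_trigger(self._window(80.0), _cal())
        assert fire and "heart-rate" in reason

    def test_heart_rate_below_30pct_does_not(self):
        fire, _ = recalibration_trigger(self._window(70.0), _cal())
        assert not fire

    def test_stiffness_change_triggers(self):
        fire, reason = recalibration_trigger(
            self._window(60.0, stiffness=0.55), _cal())
        assert fire and "stiffness" in reason

    def test_exact_30pct_is_not_persistent_excess(self):
        fire, _ = recalibration_trigger(self._window(78.0), _cal())
        assert not fire  # 30% exactly: rule is "exceeding 30%"


class TestEndToEndRecovery:
    def test_converted_bp_tracks_truth(self, induction_recording):
        """Generator linkage matches the converter model: after a single
        calibration, noise-free converted beats recover true SBP within
        1 mmHg bias and modest spread."""
        rec = induction_recording
        feats = extract_features(rec.cuff, rec.rate_hz)
        truth = rec.beat_truth
        cal = calibrate(feats, float(truth["sbp_true"].iloc[0]),
                        float(truth["dbp_true"].iloc[0]))
        out = convert_to_bp(feats, cal)
        sbp_true = np.interp(out["onset_s"], truth["onset_s"], truth["sbp_true"])
        err = out["sbp"] - sbp_true
        assert abs(err.mean()) < 1.0
        assert err.std() < 2.0
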