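"""Tests for event detection and kinematic measure extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bireach import (
    AdaptationState,
    ExperimentConfig,
    NoiseConfig,
    ReachEvents,
    TrialSpec,
    baseline_correct,
    bin_means,
    compute_measures,
    compute_rmse,
    detect_onset_offset,
    find_ballistic_end,
    find_peak_velocity,
    min_jerk_reference,
    phase_labels,
    reach_events,
    signed_angular_error,
    simulate_trial,
)
from bireach.errors import (
    BinningError,
    DetectionError,
    MissingBaselineError,
    UndefinedAngleError,
)

NOISELESS = ExperimentConfig(noise=NoiseConfig().silent())


def padded_minjerk_speed(duration=0.4, dt=0.001, pad_s=0.1):
    ref = min_jerk_reference(0.10, duration, dt)
    pad = np.zeros(int(pad_s / dt))
    return np.concatenate([pad, ref.speed, pad]), len(pad)


class TestOnsetOffset:
    def test_onset_near_true_start(self):
        speed, pad = padded_minjerk_speed()
        onset, offset = detect_onset_offset(speed, 0.001)
        assert abs(onset - pad) <= 20  # within 20 ms of the true start
        assert offset > onset
        n = len(speed)
        assert abs((n - 1 - pad) - offset) <= 20

    def test_all_zero_series_raises(self):
        with pytest.raises(DetectionError):
            detect_onset_offset(np.zeros(500), 0.001)

    def test_brief_spike_ignored(self):
        speed, pad = padded_minjerk_speed()
        speed[10] = speed.max()  # 1-sample artifact long before movement
        onset, _ = detect_onset_offset(speed, 0.001)
        assert onset > 20

    def test_offset_after_onset_contract(self, rng):
        for _ in range(20):
            dur = rng.uniform(0.3, 0.5)
            speed, _ = padded_minjerk_speed(duration=round(dur, 3))
            onset, offset = detect_onset_offset(speed, 0.001)
            assert offset > onset


class TestPeakAndBallistic:
    def test_peak_at_half_duration(self):
        speed, pad = padded_minjerk_speed(duration=0.4)
        onset, offset = detect_onset_offset(speed, 0.001)
        k = find_peak_velocity(speed, onset, offset)
        assert abs(k - (pad + 200)) <= 1

    def test_tie_broken_to_earliest(self):
        speed = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        assert find_peak_velocity(speed, 0, 4) == 1

    def test_monotone_decay_hits_zero_threshold(self):
        speed = np.concatenate([np.linspace(0, 1, 50), np.linspace(1, 0, 200)])
        k = find_ballistic_end(speed, 49, len(speed) - 1)
        assert speed[k] <= 0.01

    def test_local_minimum_of_double_peak(self):
        up = np.linspace(0, 1, 50)
        down = np.linspace(1, 0.3, 50)
        second = np.concatenate([np.linspace(0.32, 0.6, 30), np.linspace(0.6, 0.0, 40)])
        speed = np.concatenate([up, down, second])
        k = find_ballistic_end(speed, 49, len(speed) - 1)
        assert k == 99  # the valley between the two peaks
        assert k > 49


class TestSignedAngle:
    def test_collinear_zero(self):
        assert signed_angular_error((0.0, 0.05), (0.0, 0.0), (0.0, 0.10)) == 0.0

    def test_quadrant_one_negative_for_forward_target(self):
        p = (0.05 * np.cos(np.radians(45)), 0.05 * np.sin(np.radians(45)))
        ang = signed_angular_error(p, (0.0, 0.0), (0.0, 0.10))
        assert ang == pytest.approx(-45.0, abs=1e-9)

    def test_point_at_home_raises(self):
        with pytest.raises(UndefinedAngleError):
            signed_angular_error((0.0, 0.0), (0.0, 0.0), (0.0, 0.10))

    @given(st.floats(-170, 170), st.floats(0, 359))
    def test_antisymmetry_across_target_ray(self, dev, target_deg):
        th = np.radians(target_deg)
        target = (0.1 * np.cos(th), 0.1 * np.sin(th))
        pa = np.radians(target_deg + dev)
        pb = np.radians(target_deg - dev)
        a = signed_angular_error((np.cos(pa), np.sin(pa)), (0, 0), target)
        b = signed_angular_error((np.cos(pb), np.sin(pb)), (0, 0), target)
        assert a == pytest.approx(-b, abs=1e-7)


class TestRmse:
    def test_straight_reach_zero(self):
        y = np.linspace(0, 0.1, 101)
        xy = np.column_stack([np.zeros_like(y), y])
        ev = ReachEvents(0, 100, 50, 80)
        assert compute_rmse(xy, ev, (0, 0), (0, 0.1)) == 0.0

    def test_constant_offset_path(self):
        # lateral offset d over a path of length L gives d / L
        y = np.linspace(0, 0.1, 101)
        xy = np.column_stack([np.full_like(y, 0.01), y])
        ev = ReachEvents(0, 100, 50, 80)
        assert compute_rmse(xy, ev, (0, 0), (0, 0.1)) == pytest.approx(0.1, rel=1e-9)

    def test_rotation_invariance(self):
        y = np.linspace(0, 0.1, 101)
        xy = np.column_stack([0.005 * np.sin(y / 0.1 * np.pi), y])
        ev = ReachEvents(0, 100, 50, 80)
        base = compute_rmse(xy, ev, (0, 0), (0, 0.1))
        th = np.radians(33.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        assert compute_rmse(xy @ R.T, ev, (0, 0), R @ (0, 0.1)) == pytest.approx(base)


class TestComputeMeasures:
    def test_straight_on_target_all_zero(self):
        rec = simulate_trial(AdaptationState(), 0.0, TrialSpec(group="control"), NOISELESS)
        m = compute_measures(rec.samples, reach_events(rec), rec.home, rec.target)
        assert abs(m["ide_deg"]) < 0.5 and abs(m["iee_deg"]) < 0.5
        assert abs(m["fee_cm"]) < 0.05 and m["rmse"] < 0.005

    def test_fee_sign_counterclockwise_positive(self):
        y = np.linspace(0, 0.1, 101)
        x = np.linspace(0, -0.01, 101)  # ends 1 cm CCW-lateral of a forward target
        t = np.linspace(0, 0.4, 101)
        samples = np.column_stack([t, x, y, np.gradient(x, t), np.gradient(y, t),
                                   np.zeros_like(t), np.zeros_like(t)])
        ev = ReachEvents(0, 100, 50, 80)
        m = compute_measures(samples, ev, (0, 0), (0, 0.1))
        assert m["fee_cm"] == pytest.approx(1.0, abs=1e-9)

    def test_cursor_vs_hand_frame_consistency(self):
        rec = simulate_trial(
            AdaptationState(), 0.0,
            TrialSpec(group="visuomotor", block="EXP", hand="R"), NOISELESS,
        )
        ev = reach_events(rec)
        cursor = compute_measures(rec.samples, ev, rec.home, rec.target,
                                  use_cursor=True, rotation_deg_cw=45.0)
        hand = compute_measures(rec.samples, ev, rec.home, rec.target)
        assert cursor["ide_deg"] - hand["ide_deg"] == pytest.approx(-45.0, abs=1.0)

    def test_event_ordering_on_simulated_trials(self, tiny_config):
        from bireach import iter_participant_records

        _, _, recs = next(iter(iter_participant_records(tiny_config)))
        for rec in recs[:40]:
            ev = reach_events(rec)
            ev.validate()  # onset < peak <= ballistic <= offset


def _measure_frame():
    rows = []
    for hand, base_block in (("L", "KBL"), ("R", "VBL")):
        for trial, v in enumerate([2.0, 3.0, 4.0], start=1):  # baseline mean 3
            rows.append(dict(participant_id="P1", group="control", hand=hand,
                             block=base_block, trial=trial, channel=False,
                             rmse=v, ide_deg=v, iee_deg=v, fee_cm=v))
        for trial, v in enumerate([2.0, 4.0, 6.0], start=1):
            rows.append(dict(participant_id="P1", group="control", hand=hand,
                             block="EXP", trial=trial, channel=False,
                             rmse=v, ide_deg=v, iee_deg=v, fee_cm=v))
    return pd.DataFrame(rows)


class TestBaselineCorrection:
    def test_subtraction_and_zero_baseline_mean(self):
        out = baseline_correct(_measure_frame())
        exp = out[(out["block"] == "EXP") & (out["hand"] == "L")]
        assert list(exp["rmse_bc"]) == [-1.0, 1.0, 3.0]
        kbl = out[(out["block"] == "KBL") & (out["hand"] == "L")]
        assert kbl["ide_deg_bc"].mean() == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(-50, 50))
    def test_shift_invariance(self, c):
        df = _measure_frame()
        shifted = df.copy()
        for m in ("rmse", "ide_deg", "iee_deg", "fee_cm"):
            shifted[m] = shifted[m] + c
        a = baseline_correct(df)
        b = baseline_correct(shifted)
        assert np.allclose(a["rmse_bc"], b["rmse_bc"], atol=1e-9)

    def test_missing_baseline_raises(self):
        df = _measure_frame()
        with pytest.raises(MissingBaselineError):
            baseline_correct(df[df["block"] == "EXP"])


class TestBinning:
    def test_bin_count_and_first_bin_mean(self):
        rows = [dict(participant_id="P1", group="control", hand="L", block="EXP",
                     trial=i, channel=False, rmse=float(i), ide_deg=0.0,
                     iee_deg=0.0, fee_cm=0.0) for i in range(1, 251)]
        df = pd.DataFrame(rows)
        out = bin_means(df, bin_size=10, measures=["rmse"])
        assert len(out) == 25
        assert out.loc[out["bin"] == 1, "rmse"].iloc[0] == pytest.approx(5.5)

    def test_constant_series(self):
        rows = [dict(participant_id="P1", group="control", hand="L", block="EXP",
                     trial=i, channel=False, rmse=7.0, ide_deg=0.0, iee_deg=0.0,
                     fee_cm=0.0) for i in range(1, 31)]
        out = bin_means(pd.DataFrame(rows), bin_size=10, measures=["rmse"])
        assert (out["rmse"] == 7.0).all()

    def test_block_shorter_than_bin_raises(self):
        rows = [dict(participant_id="P1", group="control", hand="L", block="EXP",
                     trial=i, channel=False, rmse=1.0, ide_deg=0.0, iee_deg=0.0,
                     fee_cm=0.0) for i in range(1, 6)]
        with pytest.raises(BinningError):
            bin_means(pd.DataFrame(rows), bin_size=10, measures=["rmse"])

    def test_phase_windows(self):
        rows = [dict(participant_id="P1", group="control", hand="L",
                     block=("EXP" if i <= 250 else "POST"),
                     trial=(i if i <= 250 else i - 250), channel=False)
                for i in range(1, 301)]
        df = pd.DataFrame(rows)
        phase = phase_labels(df, window=30)
        assert (phase[:30] == "early").all()
        assert (phase[220:250] == "late").all()
        assert (phase[250:280] == "post").all()
        assert phase[30:220].isna().all()
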