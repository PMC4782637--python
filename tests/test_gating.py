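"""The three gated-acquisition sequencers and the phase sorter."""

import numpy as np
import pandas as pd
import pytest

import cinegate as cg
from cinegate.gating import GatingTimeoutError
from cinegate.physio import ParameterError


def brute_force_phase(t, peaks, n_bins):
    """Oracle: linear scan over all R peaks for one exposure time."""
    prev = None
    for i, p in enumerate(peaks):
        if p <= t:
            prev = i
    if prev is None or prev == len(peaks) - 1:
        return np.nan, np.nan
    rr = peaks[prev + 1] - peaks[prev]
    frac = (t - peaks[prev]) / rr
    return frac, min(int(frac * n_bins), n_bins - 1)


class TestProspective:
    def test_unconstrained_coincidence_hits_every_angle(self, regular_ecg, free_resp):
        cfg = cg.GatingConfig(
            n_angles=10,
            angular_step=1.0,
            resp_window=(0.0, 1.0),
            min_frame_interval=0.04,
            rotation_settle=0.05,
        )
        log = cg.prospective_sequence(
            regular_ecg.trigger_train(), free_resp, cfg, 0, max_time=30.0
        )
        assert len(log) == 10
        np.testing.assert_allclose(log.angles, np.arange(10.0))
        # zero phase delay: every exposure sits exactly on an R peak
        assert np.all(np.isin(np.round(log.times, 9), np.round(regular_ecg.r_peak_times, 9)))

    def test_zero_width_respiratory_window_times_out(self, regular_ecg, free_resp):
        cfg = cg.GatingConfig(n_angles=10, resp_window=(0.5, 0.5))
        with pytest.raises(GatingTimeoutError) as err:
            cg.prospective_sequence(
                regular_ecg.trigger_train(), free_resp, cfg, 0, max_time=20.0
            )
        assert err.value.angle_index == 0

    def test_cine_acquires_angles_times_phases(self):
        ecg = cg.simulate_ecg(1200.0, 0.2, 0.0, seed=1)
        resp = cg.simulate_ventilated_respiration(1200.0, 60.0)
        cfg = cg.GatingConfig(
            n_phases=10,
            n_angles=360,
            angular_step=1.0,
            resp_window=(0.0, 1.0),
            min_frame_interval=0.04,
            rotation_settle=0.05,
        )
        log = cg.prospective_cine(ecg.trigger_train(), resp, cfg, max_time=1200.0)
        assert len(log) == 3600
        counts = log.df.groupby("target_phase").size()
        assert (counts == 360).all()

    def test_constant_angular_increments(self, jittered_ecg, free_resp):
        cfg = cg.GatingConfig(
            n_angles=90, angular_step=2.0, resp_window=(0.0, 1.0)
        )
        log = cg.prospective_sequence(
            jittered_ecg.trigger_train(), free_resp, cfg, 0, max_time=200.0
        )
        np.testing.assert_allclose(np.diff(log.angles), 2.0)


class TestRetrospective:
    def test_pacer_count_and_spacing(self, regular_ecg, free_resp):
        cfg = cg.GatingConfig(frame_rate=10.0, n_rotations=1)
        log = cg.retrospective_acquire(
            regular_ecg.trigger_train(), free_resp, cfg, rotation_duration=36.0
        )
        assert len(log) == 360
        np.testing.assert_allclose(np.diff(log.times), 0.1, atol=1e-12)
        np.testing.assert_allclose(np.diff(log.angles)[:359], 1.0, atol=1e-9)

    def test_rotations_scale_linearly(self, regular_ecg, free_resp):
        cfg = cg.GatingConfig(frame_rate=10.0, n_rotations=5)
        log = cg.retrospective_acquire(
            regular_ecg.trigger_train(), free_resp, cfg, rotation_duration=3.6
        )
        assert len(log) == 5 * 36
        assert set(log.df["rotation"]) == set(range(5))

    def test_nonpositive_duration_rejected(self, regular_ecg, free_resp):
        with pytest.raises(ParameterError):
            cg.retrospective_acquire(
                regular_ecg.trigger_train(), free_resp, cg.GatingConfig(), 0.0
            )


class TestSortPhases:
    def test_direct_arithmetic_example(self, free_resp):
        peaks = cg.TriggerTrain(np.array([0.0, 0.2, 0.4]))
        log = cg.AcquisitionLog.from_records(
            [(0.27, 0.0, 0, np.nan, np.nan, np.nan, np.nan)]
        )
        out = cg.sort_phases(log, peaks, free_resp, cg.GatingConfig(n_phases=10))
        assert out.df["cardiac_frac"].iloc[0] == pytest.approx(0.35)
        assert out.df["cardiac_bin"].iloc[0] == 3

    def test_exposure_on_r_peak_is_bin_zero(self, free_resp):
        peaks = cg.TriggerTrain(np.array([0.0, 0.2, 0.4]))
        log = cg.AcquisitionLog.from_records(
            [(0.2, 0.0, 0, np.nan, np.nan, np.nan, np.nan)]
        )
        out = cg.sort_phases(log, peaks, free_resp, cg.GatingConfig(n_phases=10))
        assert out.df["cardiac_frac"].iloc[0] == 0.0
        assert out.df["cardiac_bin"].iloc[0] == 0

    def test_agrees_with_brute_force_oracle(self, jittered_ecg, free_resp):
        rng = np.random.default_rng(11)
        times = np.sort(rng.uniform(0.0, 199.0, 1000))
        times += np.arange(1000) * 1e-6  # enforce strict increase
        records = [(t, 0.0, 0, np.nan, np.nan, np.nan, np.nan) for t in times]
        log = cg.AcquisitionLog.from_records(records)
        cfg = cg.GatingConfig(n_phases=10)
        out = cg.sort_phases(log, jittered_ecg.trigger_train(), free_resp, cfg)
        peaks = jittered_ecg.r_peak_times
        for t, frac, b in zip(
            times, out.df["cardiac_frac"], out.df["cardiac_bin"]
        ):
            frac_o, bin_o = brute_force_phase(t, peaks, 10)
            if np.isnan(frac_o):
                assert np.isnan(frac)
            else:
                assert frac == pytest.approx(frac_o)
                assert b == bin_o

    def test_bin_counts_partition_assigned_exposures(self, jittered_ecg, free_resp):
        cfg = cg.GatingConfig()
        log = cg.retrospective_acquire(
            jittered_ecg.trigger_train(), free_resp, cfg, rotation_duration=36.0
        )
        out = cg.sort_phases(log, jittered_ecg.trigger_train(), free_resp, cfg)
        assigned = out.df["cardiac_bin"].notna()
        assert out.df.loc[assigned, "cardiac_bin"].value_counts().sum() == assigned.sum()

    def test_empty_train_rejected(self, free_resp):
        log = cg.AcquisitionLog.from_records(
            [(0.2, 0.0, 0, np.nan, np.nan, np.nan, np.nan)]
        )
        with pytest.raises(ParameterError):
            cg.sort_phases(
                log, cg.TriggerTrain(np.array([])), free_resp, cg.GatingConfig()
            )


class TestEmaPredict:
    def test_constant_history_is_fixed_point(self):
        assert cg.ema_predict([0.15] * 20, 0.3) == pytest.approx(0.15)

    def test_alpha_one_returns_last_value(self):
        assert cg.ema_predict([0.15, 0.2, 0.18], 1.0) == 0.18

    def test_two_sample_recursion_by_hand(self):
        assert cg.ema_predict([0.15, 0.16], 0.5) == pytest.approx(0.155)

    def test_step_change_decays_geometrically(self):
        alpha = 0.3
        rr = [0.1] * 5 + [0.2] * 30
        series = cg.ema_series(rr, alpha)
        err = np.abs(series[5:] - 0.2)
        ratios = err[1:] / err[:-1]
        np.testing.assert_allclose(ratios, 1.0 - alpha, atol=1e-9)

    def test_empty_history_rejected(self):
        with pytest.raises(ParameterError):
            cg.ema_predict([], 0.5)


class TestFpg:
    def _config(self, **kw):
        base = dict(
            n_phases=10,
            n_angles=30,
            angular_step=1.0,
            min_frame_interval=0.04,
            rotation_settle=0.05,
        )
        base.update(kw)
        return cg.GatingConfig(**base)

    def test_every_angle_gets_all_phases(self, jittered_ecg):
        cfg = self._config()
        log = cg.fpg_sequence(jittered_ecg.trigger_train(), cfg, max_time=200.0)
        assert len(log) == 30 * 10
        per_angle = log.df.groupby("angle_deg").size()
        assert (per_angle == 10).all()

    def test_slow_heart_packs_one_beat_per_angle(self):
        # RR 0.5 s, dead time 40 ms: all 10 phases fit within a single beat
        ecg = cg.simulate_ecg(120.0, 0.5, 0.0, seed=0)
        cfg = self._config(n_angles=20)
        log = cg.fpg_sequence(ecg.trigger_train(), cfg, max_time=120.0)
        assert len(log) == 200
        for _, grp in log.df.groupby("angle_deg"):
            assert grp["time_s"].max() - grp["time_s"].min() < 0.5

    def test_fast_heart_defers_across_beats(self):
        # RR 150 ms with 100 ms dead time: phases must spread over >= 10 beats
        ecg = cg.simulate_ecg(300.0, 0.15, 0.0, seed=0)
        cfg = self._config(n_angles=5, min_frame_interval=0.1)
        log = cg.fpg_sequence(ecg.trigger_train(), cfg, max_time=300.0)
        assert len(log) == 50
        peaks = ecg.r_peak_times
        for _, grp in log.df.groupby("angle_deg"):
            t = grp["time_s"].to_numpy()
            n_beats = (
                np.searchsorted(peaks, t.max()) - np.searchsorted(peaks, t.min())
            )
            assert n_beats >= 9
            # greedy earliest-feasible-beat: consecutive exposures obey dead time
            assert np.all(np.diff(t) >= 0.1 - 1e-9)

    def test_matches_greedy_scheduling_oracle(self):
        """Constant RR: each phase lands in the first beat where its delay
        clears the dead time after the previous exposure."""
        rr, mfi = 0.15, 0.1
        ecg = cg.simulate_ecg(60.0, rr, 0.0, seed=0)
        cfg = self._config(n_angles=1, min_frame_interval=mfi)
        log = cg.fpg_sequence(ecg.trigger_train(), cfg, max_time=60.0)

        peaks = ecg.r_peak_times
        expected, last, k = [], -np.inf, 1
        for frac in cfg.phase_fracs:
            while peaks[k] + frac * rr < last + mfi - 1e-9:
                k += 1
            te = peaks[k] + frac * rr
            expected.append(te)
            last = te
        np.testing.assert_allclose(log.times, expected, atol=1e-9)

    def test_timeout_reports_progress(self, regular_ecg):
        cfg = self._config(n_angles=360)
        with pytest.raises(GatingTimeoutError) as err:
            cg.fpg_sequence(regular_ecg.trigger_train(), cfg, max_time=5.0)
        assert err.value.n_acquired > 0


class TestCrossStrategyProperties:
    def test_fpg_faster_than_prospective_cine(self, jittered_ecg):
        """Per-angle multi-phase acquisition beats sequential full sets."""
        resp = cg.simulate_ventilated_respiration(1000.0, 60.0, 0.4)
        ecg = cg.simulate_ecg(1000.0, 0.143, 0.008, seed=5)
        cfg = cg.GatingConfig(
            n_phases=10,
            n_angles=30,
            angular_step=1.0,
            resp_window=(0.85, 1.0),
            min_frame_interval=0.04,
            rotation_settle=0.05,
        )
        pro = cg.prospective_cine(ecg.trigger_train(), resp, cfg, max_time=1000.0)
        fpg = cg.fpg_sequence(ecg.trigger_train(), cfg, max_time=1000.0)
        assert len(pro) == len(fpg) == 300
        assert fpg.times[-1] < pro.times[-1]

    def test_no_log_violates_min_frame_interval(self, jittered_ecg, free_resp):
        cardiac = jittered_ecg.trigger_train()
        cfg = cg.GatingConfig(
            n_angles=30,
            resp_window=(0.0, 1.0),
            min_frame_interval=0.1,
            rotation_settle=0.05,
        )
        logs = [
            cg.prospective_sequence(cardiac, free_resp, cfg, 0, max_time=200.0),
            cg.retrospective_acquire(cardiac, free_resp, cfg, 36.0),
            cg.fpg_sequence(cardiac, cfg, max_time=200.0),
        ]
        for log in logs:
            assert np.all(np.diff(log.times) >= cfg.min_frame_interval - 1e-9)

    def test_retrospective_bins_have_irregular_angles(self, jittered_ecg, free_resp):
        """Generic rotation period: per-bin angular gaps are uneven."""
        cfg = cg.GatingConfig(n_rotations=2)
        log = cg.retrospective_acquire(
            jittered_ecg.trigger_train(), free_resp, cfg, 36.0
        )
        out = cg.sort_phases(log, jittered_ecg.trigger_train(), free_resp, cfg)
        df = out.df[out.df["cardiac_bin"] == 0]
        angles = np.sort(np.mod(df["angle_deg"].to_numpy(), 360.0))
        gaps = np.diff(angles)
        gaps = gaps[gaps > 1e-9]
        assert gaps.max() / gaps.min() > 1.0
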