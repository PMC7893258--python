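"""Glide detection and segmentation against planted synthetic records."""

import numpy as np
import pytest

from whalebody.hydro import HydroParams, glide_acceleration
from whalebody.kinematics import (
    CtdProfile,
    GlideDetectionConfig,
    GlideObservation,
    PitchBelowFloorError,
    TagTimeSeries,
    detect_glides,
    filter_whales,
    pitch_from_triaxial,
    segment_glides,
    speed_from_depth_rate,
)
from whalebody.synthetic import TimeSeriesSimConfig, simulate_ctd, simulate_timeseries


class TestSpeedFromDepthRate:
    def test_vertical_dive(self):
        assert speed_from_depth_rate(1.2, -np.pi / 2) == pytest.approx(1.2)

    def test_thirty_degrees(self):
        assert speed_from_depth_rate(0.6, np.pi / 6) == pytest.approx(1.2)

    def test_below_floor_raises(self):
        with pytest.raises(PitchBelowFloorError):
            speed_from_depth_rate(0.5, 0.05, pitch_floor=0.52)

    def test_array_input_nan_below_floor(self):
        v = speed_from_depth_rate(
            np.array([0.6, 0.6]), np.array([np.pi / 6, 0.05]), pitch_floor=0.52
        )
        assert v[0] == pytest.approx(1.2)
        assert np.isnan(v[1])

    def test_scale_equivariance(self):
        v1 = speed_from_depth_rate(0.7, 0.9)
        v2 = speed_from_depth_rate(1.4, 0.9)
        assert v2 == pytest.approx(2.0 * v1)


class TestTagTimeSeriesInvariants:
    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.2, 0.5, 0.6])
        with pytest.raises(ValueError, match="non-uniform"):
            TagTimeSeries(time=t, depth=np.zeros(4), accel_dv=np.zeros(4))

    def test_negative_depth_rejected(self):
        t = np.arange(4) * 0.2
        with pytest.raises(ValueError, match="depth"):
            TagTimeSeries(time=t, depth=np.array([0.0, -1.0, 0.0, 0.0]),
                          accel_dv=np.zeros(4))

    def test_pitch_range_enforced(self):
        t = np.arange(4) * 0.2
        with pytest.raises(ValueError, match="pitch"):
            TagTimeSeries(time=t, depth=np.zeros(4), accel_dv=np.zeros(4),
                          pitch=np.array([0.0, 2.0, 0.0, 0.0]))


class TestDetectGlides:
    def test_strokes_everywhere_yields_nothing(self):
        series, _ = simulate_timeseries(TimeSeriesSimConfig(glide_windows=()), seed=2)
        assert detect_glides(series) == []

    def test_planted_windows_recovered_within_a_second(self):
        cfg = TimeSeriesSimConfig(glide_windows=((20.0, 32.0), (130.0, 137.0)))
        series, truth = simulate_timeseries(cfg, seed=1)
        found = detect_glides(series)
        assert len(found) == 2
        for (t0, t1), (f0, f1) in zip(truth["windows"], found):
            assert abs(f0 - t0) <= 1.0
            assert abs(f1 - t1) <= 1.0
            # detected window never grows beyond the stroke-free truth
            assert f0 >= t0 - 0.21 and f1 <= t1 + 0.21

    def test_windows_do_not_overlap_and_are_long_enough(self):
        cfg = TimeSeriesSimConfig(
            glide_windows=((10.0, 18.0), (25.0, 40.0), (100.0, 106.0))
        )
        series, _ = simulate_timeseries(cfg, seed=3)
        found = detect_glides(series)
        for (a0, a1), (b0, b1) in zip(found, found[1:]):
            assert a1 <= b0
        assert all(t1 - t0 >= 5.0 for t0, t1 in found)


class TestSegmentGlides:
    def _flat_ctd(self):
        return simulate_ctd(gradient=0.0)

    def _series(self, t, depth, pitch, speed):
        return TagTimeSeries(
            time=t, depth=depth, accel_dv=np.zeros_like(t), pitch=pitch,
            speed=speed, whale_id="w0",
        )

    def test_exact_linear_speed(self):
        t = np.arange(0.0, 5.01, 0.2)
        v = 1.0 + 0.1 * t
        s = self._series(t, np.full_like(t, 20.0), np.full_like(t, 0.7), v)
        obs = segment_glides([(0.0, 5.0)], s, self._flat_ctd())
        assert len(obs) == 1
        assert obs[0].accel == pytest.approx(0.1, abs=1e-12)
        assert obs[0].accel_se == pytest.approx(0.0, abs=1e-9)

    def test_ols_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 5.01, 0.2)
        v = 1.4 + 0.05 * t + 0.02 * rng.standard_normal(t.size)
        s = self._series(t, np.full_like(t, 20.0), np.full_like(t, 0.7), v)
        obs = segment_glides([(0.0, 5.0)], s, self._flat_ctd())[0]
        # brute-force normal equations
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        resid = v - X @ beta
        sigma2 = resid @ resid / (t.size - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert obs.accel == pytest.approx(beta[1], rel=1e-9)
        assert obs.accel_se == pytest.approx(se, rel=1e-6)

    def test_twelve_second_window_tiles_into_two_segments(self):
        t = np.arange(0.0, 12.01, 0.2)
        s = self._series(t, np.full_like(t, 20.0), np.full_like(t, 0.7),
                         np.full_like(t, 1.5))
        obs = segment_glides([(0.0, 12.0)], s, self._flat_ctd())
        assert len(obs) == 2

    def test_forward_model_consistency_noise_free(self):
        # single 5 s glide with incompressible tissue, no air term and a
        # constant-density profile: OLS acceleration equals the forward
        # model at the segment means to machine precision
        cfg = TimeSeriesSimConfig(glide_windows=((20.0, 25.0),), accel_noise=0.0)
        series, truth = simulate_timeseries(cfg, seed=3)
        obs = segment_glides([(20.0, 25.0)], series, cfg.ctd)[0]
        params = HydroParams(**truth["params"])
        pred = glide_acceleration(params, obs.depth, obs.pitch, obs.speed, obs.rho_sw)
        assert obs.accel == pytest.approx(pred, abs=1e-6)

    def test_near_horizontal_segments_dropped_without_propeller(self):
        # resting at the surface: flat depth, near-zero pitch, no speed channel
        t = np.arange(0.0, 20.01, 0.2)
        s = TagTimeSeries(
            time=t, depth=np.full_like(t, 0.5), accel_dv=np.zeros_like(t),
            pitch=np.full_like(t, 0.02), whale_id="w0",
        )
        assert segment_glides([(0.0, 20.0)], s, self._flat_ctd()) == []

    def test_rho_sw_interpolated_at_segment_depth(self):
        ctd = CtdProfile(depth=np.array([0.0, 100.0]),
                         density=np.array([1020.0, 1030.0]))
        t = np.arange(0.0, 5.01, 0.2)
        s = self._series(t, np.full_like(t, 50.0), np.full_like(t, 0.7),
                         np.full_like(t, 1.5))
        obs = segment_glides([(0.0, 5.0)], s, ctd)[0]
        assert obs.rho_sw == pytest.approx(1025.0)


class TestPitchFromTriaxial:
    def test_static_surge_recovered(self):
        fs, f_stroke = 10.0, 0.4
        t = np.arange(0.0, 120.0, 1.0 / fs)
        pitch_true = np.deg2rad(35.0)
        surge = 9.8 * np.sin(pitch_true) + 0.8 * np.sin(2 * np.pi * f_stroke * t)
        est = pitch_from_triaxial(surge, fs, f_stroke)
        mid = slice(int(20 * fs), int(100 * fs))  # away from filter edges
        assert np.median(est[mid]) == pytest.approx(pitch_true, abs=0.02)


class TestFilterWhales:
    def _glides(self, counts):
        out = []
        for w, c in counts.items():
            out += [
                GlideObservation(w, 0, 50.0, 0.7, 1.5, 1026.0, 0.01, 0.01)
                for _ in range(c)
            ]
        return out

    def test_boundary_at_ten_glides(self):
        glides = self._glides({"A": 9, "B": 10})
        kept, excluded = filter_whales(glides, min_glides=10)
        assert excluded == ["A"]
        assert {g.whale_id for g in kept} == {"B"}

    def test_study_scale_exclusion(self):
        # 70 whales, 11 of them with fewer than 10 glides -> 59 retained
        counts = {f"w{i:02d}": (5 if i < 11 else 12) for i in range(70)}
        kept, excluded = filter_whales(self._glides(counts), min_glides=10)
        assert len(excluded) == 11
        assert len({g.whale_id for g in kept}) == 59

    def test_min_glides_validated(self):
        with pytest.raises(ValueError):
            filter_whales([], min_glides=0)
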