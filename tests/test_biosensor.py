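"""Biosensor trace summarization: AUC phases, peak, plateau, normalizations."""

import numpy as np
import pytest

from acquant import (
    Calibration,
    ImageStack,
    KineticConfig,
    TimeSeries,
    biosensor_response,
    fskibmx_normalize,
    integrate_phase,
    normalize_to_condition,
    peak_time,
    peak_value,
    plateau_value,
    roi_trace,
    simulate_biosensor_trace,
    summarize_phases,
)


def _trace(values, times=None, **kw):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return TimeSeries(np.asarray(times, dtype=float), values, normalization="dF/F0", **kw)


def _grid(stop_min=32.0):
    n = int(round(stop_min * 3)) + 4  # 20 s sampling from t = -1 min
    return (np.arange(n) - 3) / 3.0


class TestFskNormalize:
    def test_divides_by_epoch_mean(self):
        trace = _trace([2.0, 2.0, 4.0, 4.0], fsk_frames=(2, 4))
        out = fskibmx_normalize(trace)
        np.testing.assert_allclose(out.values, [0.5, 0.5, 1.0, 1.0])

    def test_trace_equal_to_its_epoch_mean_maps_to_one(self):
        trace = _trace([3.0] * 5, fsk_frames=(3, 5))
        np.testing.assert_allclose(fskibmx_normalize(trace).values, 1.0)

    def test_recovers_plateau_over_saturation_within_one_percent(self):
        kin = KineticConfig(noise_sd=0.0, tau_decay_min=5.0)
        trace, truth = simulate_biosensor_trace(kin)
        out = fskibmx_normalize(trace)
        measured = plateau_value(out)
        # late plateau of r(t)/S approaches p*A/S once the decay has relaxed
        expected = kin.plateau_fraction * kin.amplitude / kin.fsk_level
        assert measured == pytest.approx(expected, rel=0.01)

    def test_nonpositive_epoch_mean_errors(self):
        trace = _trace([1.0, 1.0, 0.0, 0.0], fsk_frames=(2, 4))
        with pytest.raises(ValueError, match="positive"):
            fskibmx_normalize(trace)


class TestIntegratePhase:
    def test_zero_trace(self):
        times = _grid(30.0)
        trace = _trace(np.zeros(times.size), times=times)
        assert integrate_phase(trace, 0.0, 5.0) == 0.0

    def test_constant_rectangle(self):
        times = _grid(30.0)
        trace = _trace(np.ones(times.size), times=times)
        assert integrate_phase(trace, 0.0, 5.0) == pytest.approx(5.0, rel=1e-12)

    @pytest.mark.parametrize("tau", [2.0, 5.0, 10.0])
    def test_exponential_within_one_percent_of_closed_form(self, tau):
        times = _grid(30.0)
        a = 0.7
        trace = _trace(np.where(times >= 0, a * np.exp(-np.clip(times, 0, None) / tau), 0.0),
                       times=times)
        T = 30.0
        closed = a * tau * (1.0 - np.exp(-T / tau))
        assert integrate_phase(trace, 0.0, T) == pytest.approx(closed, rel=0.01)

    def test_additivity_to_machine_precision(self):
        kin = KineticConfig(seed=3)
        trace, _ = simulate_biosensor_trace(kin)
        total = integrate_phase(trace, 0.0, 30.0)
        parts = integrate_phase(trace, 0.0, 5.0) + integrate_phase(trace, 5.0, 30.0)
        assert parts == pytest.approx(total, rel=1e-9)

    def test_boundary_interpolation_off_grid(self):
        # samples at 0,1,2: integral over [0.5, 1.5] of the ramp v=t is 1.0
        trace = _trace([0.0, 1.0, 2.0], times=[0.0, 1.0, 2.0])
        assert integrate_phase(trace, 0.5, 1.5) == pytest.approx(1.0, rel=1e-12)

    def test_window_outside_span_errors(self):
        trace = _trace([1.0, 1.0], times=[0.0, 1.0])
        with pytest.raises(ValueError, match="span"):
            integrate_phase(trace, 0.0, 5.0)

    def test_nan_samples_interpolated_for_auc_only(self):
        times = _grid(30.0)
        values = np.ones(times.size)
        values[30] = np.nan
        trace = _trace(values, times=times)
        assert integrate_phase(trace, 0.0, 30.0) == pytest.approx(30.0, rel=1e-9)
        assert np.isnan(trace.values[30])  # stored trace untouched


class TestPeakAndPlateau:
    def test_peak_of_toy_samples(self):
        trace = _trace([0.0, 1.0, 3.0, 2.0])
        assert peak_value(trace, (0.0, 3.0)) == 3.0

    def test_monotone_trace_peaks_at_last_sample(self):
        times = _grid(30.0)
        trace = _trace(np.linspace(0, 1, times.size), times=times)
        assert peak_value(trace) == trace.values[times <= 30.0][-1]

    def test_peak_matches_grid_maximum_of_formula(self):
        kin = KineticConfig(noise_sd=0.0)
        trace, _ = simulate_biosensor_trace(kin)
        sel = (trace.times_min > 0) & (trace.times_min <= 30.0)
        grid_max = biosensor_response(
            trace.times_min[sel], kin.amplitude, kin.tau_rise_min,
            kin.tau_decay_min, kin.plateau_fraction,
        ).max()
        assert peak_value(trace) == pytest.approx(grid_max, rel=1e-12)

    def test_peak_search_excludes_pre_agonist_frames(self):
        trace = _trace([9.0, 0.5, 1.0, 0.8], times=[-1.0, 1.0, 2.0, 3.0])
        assert peak_value(trace, (0.0, 3.0)) == 1.0

    def test_tied_peak_reports_earliest_time(self):
        trace = _trace([0.0, 2.0, 1.0, 2.0], times=[1.0, 2.0, 3.0, 4.0])
        assert peak_time(trace, (0.0, 4.0)) == 2.0

    def test_plateau_of_constant(self):
        times = _grid(30.0)
        trace = _trace(np.full(times.size, 0.4), times=times)
        assert plateau_value(trace) == pytest.approx(0.4)

    def test_plateau_of_dense_ramp_is_midpoint(self):
        times = np.linspace(20.0, 30.0, 1001)
        trace = _trace(np.linspace(0.0, 1.0, times.size), times=times)
        assert plateau_value(trace) == pytest.approx(0.5, abs=5e-3)

    def test_plateau_equals_grid_mean_of_ground_truth(self):
        kin = KineticConfig(noise_sd=0.0)
        trace, truth = simulate_biosensor_trace(kin)
        window = (trace.times_min >= 20.0) & (trace.times_min <= 30.0)
        assert plateau_value(trace) == pytest.approx(
            truth.expected_trace[window].mean(), rel=1e-9
        )

    def test_plateau_never_exceeds_peak_for_nonnegative_traces(self):
        for seed in range(5):
            trace, _ = simulate_biosensor_trace(KineticConfig(noise_sd=0.0, seed=seed))
            assert plateau_value(trace) <= peak_value(trace)


class TestScaleEquivariance:
    def test_statistics_scale_with_trace(self):
        trace, _ = simulate_biosensor_trace(KineticConfig(seed=2))
        c = 3.7
        scaled = _trace(trace.values * c, times=trace.times_min,
                        fsk_frames=trace.fsk_frames)
        a, b = summarize_phases(trace), summarize_phases(scaled)
        for stat in ("auc_early", "auc_late", "auc_total", "peak", "plateau"):
            assert getattr(b, stat) == pytest.approx(c * getattr(a, stat), rel=1e-12)


class TestConditionNormalization:
    @staticmethod
    def _summary(cell_id, condition, value):
        from acquant import PhaseSummary

        return PhaseSummary(cell_id, condition, value, value, value, value, value)

    def test_reference_mean_two_value_three_maps_to_1p5(self):
        sums = [self._summary("a", "ref", 2.0), self._summary("b", "mut", 3.0)]
        out = normalize_to_condition(sums, "ref")
        assert out.loc[out["condition"] == "mut", "peak"].iloc[0] == pytest.approx(1.5)

    def test_reference_condition_normalizes_to_unit_mean(self):
        sums = [self._summary(str(i), "ref", v) for i, v in enumerate([1.0, 2.0, 3.0])]
        out = normalize_to_condition(sums, "ref")
        assert out["plateau"].mean() == pytest.approx(1.0)

    def test_recovers_programmed_plateau_ratio_at_n9(self, rng):
        from acquant import matched_peak_variant, summarize_phases

        base = KineticConfig()
        variant = matched_peak_variant(base, plateau_ratio=0.5)
        sums = []
        for cond, kin in (("AC9", base), ("AC9-LL>AA", variant)):
            for i in range(9):
                k = KineticConfig(**{**kin.__dict__, "seed": int(rng.integers(2**31))})
                trace, _ = simulate_biosensor_trace(k)
                sums.append(summarize_phases(trace, cell_id=f"{cond}{i}", condition=cond))
        out = normalize_to_condition(sums, "AC9")
        mut_plateau = out.loc[out["condition"] == "AC9-LL>AA", "plateau"].mean()
        # sampling error at n = 9 with sd(plateau)/plateau ~ noise/sqrt(frames)
        assert mut_plateau == pytest.approx(0.5, abs=0.05)

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            normalize_to_condition([self._summary("a", "x", 1.0)], "ref")


class TestRoiTrace:
    @staticmethod
    def _movie(frames, agonist_frame=3):
        pixels = np.asarray(frames, dtype=float)[:, None, None]
        cal = Calibration(pixel_size_um=0.1, frame_interval_s=20.0,
                          agonist_frame=agonist_frame)
        return ImageStack(pixels, cal)

    def test_constant_movie_gives_zero_dff0(self):
        movie = self._movie(np.full((10, 8, 8), 7.0))
        roi = np.zeros((8, 8), dtype=bool)
        roi[2:6, 2:6] = True
        out = roi_trace(movie, roi, background=0.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_recovers_painted_response_exactly(self):
        times_min = (np.arange(10) - 3) * 20.0 / 60.0
        r = biosensor_response(times_min, 0.5, 1.0, 8.0, 0.6)
        f0 = 40.0
        frames = np.full((10, 12, 12), 5.0)
        roi = np.zeros((12, 12), dtype=bool)
        roi[3:9, 3:9] = True
        for i in range(10):
            frames[i][roi] = 5.0 + f0 * (1.0 + r[i])
        out = roi_trace(self._movie(frames), roi, background=5.0)
        np.testing.assert_allclose(out.values, r, rtol=1e-9, atol=1e-12)

    def test_roi_outside_cell_stays_near_zero(self, rng):
        frames = rng.normal(10.0, 0.5, size=(10, 16, 16))
        frames[:, 2:8, 2:8] += 50.0
        roi = np.zeros((16, 16), dtype=bool)
        roi[10:14, 10:14] = True
        out = roi_trace(self._movie(frames), roi, background=10.0, mode="raw")
        # raw background-subtracted means fluctuate at the noise level only
        assert np.abs(out.values).max() < 3 * 0.5 / np.sqrt(roi.sum())

    def test_empty_roi_errors(self):
        movie = self._movie(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            roi_trace(movie, np.zeros((4, 4), dtype=bool))
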