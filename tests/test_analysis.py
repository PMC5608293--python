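"""Trace analytics: segmentation, OLS fits, duty cycle, plateau stability,
aggregation, and the calibration inverse."""

import math

import numpy as np
import pytest
from hypothesis import given, assume, strategies as st

import microtherm as mt


def synthetic_trace(times, temps, relay=None):
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps, dtype=float)
    relay = np.zeros(len(times), bool) if relay is None else np.asarray(relay, bool)
    return mt.Trace(time=times, t1_raw=temps, t1_filt=temps,
                    t2=np.full(len(times), 37.0), relay=relay)


class TestSegmentTrace:
    def test_reference_run_yields_three_ramps(self, reference_run):
        trace, _ = reference_run
        seg = mt.segment_trace(trace, [30, 40, 42, 44])
        assert not seg.truncated
        assert len(seg.segments) == 3
        assert all(s.complete for s in seg.segments)

    def test_never_reached_breakpoint_is_flagged(self):
        t = np.arange(100) * 0.1
        temps = np.minimum(30.0 + t, 38.0)  # plateaus below 40
        trace = synthetic_trace(t, temps)
        with pytest.warns(UserWarning, match="never reached"):
            seg = mt.segment_trace(trace, [30, 40, 42])
        assert seg.truncated
        assert len(seg.segments) == 1
        assert not seg.segments[0].complete

    def test_known_crossings_give_exact_boundaries(self):
        # piecewise-linear monotone ramp: 1 °C per row from 30 to 45
        t = np.arange(16.0)
        temps = 30.0 + t
        trace = synthetic_trace(t, temps)
        seg = mt.segment_trace(trace, [30, 40, 42, 44], crossing_tol=0.0)
        spans = [(s.times[0], s.times[-1]) for s in seg.segments]
        assert spans == [(0.0, 9.0), (10.0, 11.0), (12.0, 13.0)]

    def test_bad_breakpoints_rejected(self, reference_run):
        trace, _ = reference_run
        with pytest.raises(mt.AnalysisError):
            mt.segment_trace(trace, [40, 40])


class TestFitSegment:
    def test_exact_line(self):
        t = np.linspace(0, 5, 20)
        fit = mt.fit_segment(t, 2.0 * t + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_tent_has_zero_slope(self):
        fit = mt.fit_segment([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0 / 3.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=-10, max_value=10),
                st.floats(min_value=-100, max_value=100),
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_matches_normal_equations_oracle(self, points):
        t = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        assume(np.ptp(t) > 1e-3 and np.ptp(y) > 1e-3)
        n = len(t)
        ata = np.array([[n, t.sum()], [t.sum(), (t * t).sum()]])
        atb = np.array([y.sum(), (t * y).sum()])
        intercept, slope = np.linalg.solve(ata, atb)
        fit = mt.fit_segment(t, y)
        scale = max(1.0, abs(slope), abs(intercept))
        assert abs(fit.slope - slope) <= 1e-9 * scale
        assert abs(fit.intercept - intercept) <= 1e-9 * scale

    def test_zero_variance_response_warns_r2_zero(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = mt.fit_segment([0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        assert fit.r_squared == 0.0
        assert fit.slope == 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(mt.AnalysisError):
            mt.fit_segment([1.0], [2.0])
        with pytest.raises(mt.AnalysisError):
            mt.fit_segment([1.0, 1.0], [2.0, 3.0])


class TestDutyCycle:
    def test_always_on(self):
        log = mt.RelayLog(times=np.array([0.0]), states=np.array([True]))
        assert mt.duty_cycle(log, (0.0, 10.0)).on_fraction == 1.0

    def test_hand_computed_quarter(self):
        log = mt.RelayLog(times=np.array([0.0, 1.0]), states=np.array([True, False]))
        report = mt.duty_cycle(log, (0.0, 4.0))
        assert report.on_fraction == pytest.approx(0.25, abs=1e-12)
        assert report.n_cycles == 1

    def test_window_clipping(self):
        log = mt.RelayLog(times=np.array([0.0, 2.0, 3.0, 5.0]),
                          states=np.array([True, False, True, False]))
        report = mt.duty_cycle(log, (1.0, 4.0))
        assert report.on_fraction == pytest.approx((1.0 + 1.0) / 3.0, abs=1e-12)
        assert report.n_cycles == 2

    @given(
        st.lists(st.floats(min_value=0.01, max_value=2.0), min_size=2, max_size=12),
        st.floats(min_value=0.0, max_value=3.0),
        st.floats(min_value=0.5, max_value=8.0),
    )
    def test_matches_dense_grid_oracle(self, gaps, w0, width):
        """on_fraction agrees with brute-force integration of the relay
        step function on a dense grid (splitting-invariance in effect)."""
        times = np.cumsum(gaps)
        states = np.array([i % 2 == 0 for i in range(len(times))])  # on, off, on, ...
        log = mt.RelayLog(times=times, states=states)
        window = (w0, w0 + width)
        grid = np.linspace(window[0], window[1], 20001)
        state_at = np.zeros(len(grid), bool)
        for t, s in zip(times, states):
            state_at[grid >= t] = s
        oracle = state_at.mean()
        report = mt.duty_cycle(log, window)
        assert report.on_fraction == pytest.approx(oracle, abs=2e-3)

    def test_inverted_window_rejected(self):
        log = mt.RelayLog(times=np.array([0.0]), states=np.array([True]))
        with pytest.raises(mt.AnalysisError):
            mt.duty_cycle(log, (2.0, 1.0))


class TestPlateauStats:
    def test_constant_plateau(self):
        t = np.arange(100) * 0.01
        trace = synthetic_trace(t, np.full(100, 42.0))
        stats = mt.plateau_stats(trace, (0.0, 1.0), 42.0, 0.1)
        assert stats.sd == 0.0 and stats.max_excursion == 0.0
        assert stats.mean == 42.0

    def test_alternating_readings(self):
        t = np.arange(10) * 0.1
        temps = np.where(np.arange(10) % 2 == 0, 41.9, 42.1)
        trace = synthetic_trace(t, temps)
        stats = mt.plateau_stats(trace, (0.0, 1.0), 42.0, 0.1)
        assert stats.mean == pytest.approx(42.0)
        assert stats.max_excursion == pytest.approx(0.1, abs=1e-12)

    def test_sinusoid_sd_closed_form(self):
        t = np.linspace(0, 10, 100_001)
        amplitude = 0.3
        trace = synthetic_trace(t, 42.0 + amplitude * np.sin(2 * np.pi * t))
        stats = mt.plateau_stats(trace, (0.0, 10.0), 42.0, 0.1)
        assert stats.sd == pytest.approx(amplitude / math.sqrt(2), rel=0.01)

    def test_empty_window_rejected(self, reference_run):
        trace, _ = reference_run
        with pytest.raises(mt.AnalysisError):
            mt.plateau_stats(trace, (5.0, 5.0), 42.0, 0.1)


class TestTimeToSetpoint:
    def test_trace_already_at_setpoint(self):
        trace = synthetic_trace([0.0, 1.0], [42.0, 42.0])
        assert mt.time_to_setpoint(trace, 42.0) == 0.0

    def test_reference_run_matches_ramp_oracle(self, reference_run):
        trace, _ = reference_run
        t = mt.time_to_setpoint(trace, 40.0)
        assert t == pytest.approx(10.0 / 3.375, abs=0.01 + 1e-9)

    def test_never_reached_raises(self):
        trace = synthetic_trace([0.0, 1.0], [30.0, 31.0], relay=[True, True])
        with pytest.raises(mt.SetpointNotReachedError):
            mt.time_to_setpoint(trace, 42.0)


class TestAggregate:
    def test_identical_replicates_have_zero_sd(self, reference_run):
        trace, _ = reference_run
        grid = np.linspace(trace.time[0], trace.time[-1], 50)
        agg = mt.aggregate_traces([trace] * 10, grid)
        assert agg.n == 10
        assert np.allclose(agg.sd, 0.0, atol=1e-12)

    def test_two_constant_traces(self):
        a = synthetic_trace([0.0, 1.0], [1.0, 1.0])
        b = synthetic_trace([0.0, 1.0], [3.0, 3.0])
        agg = mt.aggregate_traces([a, b], np.array([0.0, 0.5, 1.0]))
        assert np.allclose(agg.mean, 2.0)
        assert np.allclose(agg.sd, math.sqrt(2.0))

    def test_single_trace_returns_itself_interpolated(self, reference_run):
        trace, _ = reference_run
        agg = mt.aggregate_traces([trace], trace.time[:100])
        assert np.array_equal(agg.mean, trace.t1_filt[:100])
        assert np.all(agg.sd == 0.0)

    def test_ten_noisy_replicates(self, reference_rig):
        """Seeded noisy replicates: grid-length arrays, SD > 0 on the ramp."""
        plant, _, _, _ = reference_rig
        ctrl = mt.ControllerConfig(stages=((40.0, 1.0),))
        sensor = mt.SensorSpec(noise_sd=0.05)
        traces = [
            mt.run_experiment(mt.ProtocolSpec(seed=s), plant, sensor, ctrl)[0]
            for s in range(10)
        ]
        t_end = min(tr.time[-1] for tr in traces)
        grid = np.linspace(0.0, t_end, 200)
        agg = mt.aggregate_traces(traces, grid)
        assert len(agg.mean) == len(grid) == len(agg.sd)
        ramp = (grid > 0.5) & (grid < 2.5)
        assert np.all(agg.sd[ramp] > 0)

    def test_grid_outside_span_rejected(self):
        a = synthetic_trace([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(mt.AnalysisError):
            mt.aggregate_traces([a], np.array([0.0, 2.0]))
        with pytest.raises(mt.AnalysisError):
            mt.aggregate_traces([], np.array([0.0, 1.0]))


class TestCalibration:
    def test_lossless_limit(self):
        params = mt.calibrate_from_observations((1.0, 2.0), 0.0, (30.0, 40.0, 50.0))
        assert params.loss_rate == 0.0
        assert [h for _, _, h in params.heat_rates] == [1.0, 2.0]

    def test_printed_observations_closed_form(self):
        params = mt.calibrate_from_observations(
            mt.REFERENCE_NET_SLOPES, mt.REFERENCE_DUTY, mt.REFERENCE_BREAKPOINTS
        )
        expected_loss = 0.205 * 0.291 / (1.0 - 0.205)
        assert params.loss_rate == pytest.approx(expected_loss, rel=1e-12)
        assert params.loss_rate == pytest.approx(0.0750, abs=5e-5)
        gross = [h for _, _, h in params.heat_rates]
        assert gross == pytest.approx(
            [s + expected_loss for s in mt.REFERENCE_NET_SLOPES], rel=1e-12
        )
        assert gross == pytest.approx([3.450, 0.366, 0.211], abs=5e-5)

    def test_invalid_observations_rejected(self):
        with pytest.raises(mt.AnalysisError):
            mt.calibrate_from_observations((1.0,), 1.0, (30.0, 40.0))
        with pytest.raises(mt.AnalysisError):
            mt.calibrate_from_observations((-1.0,), 0.2, (30.0, 40.0))
        with pytest.raises(mt.AnalysisError):
            mt.calibrate_from_observations((1.0,), 0.2, (30.0, 40.0, 50.0))

    def test_round_trip_recovers_observations(self, reference_run):
        """Calibrate -> simulate noiselessly -> re-measure slopes and duty:
        the printed observations are recovered within 2 %."""
        trace, relay = reference_run
        seg = mt.segment_trace(trace, mt.REFERENCE_BREAKPOINTS)
        slopes = [mt.fit_segment(s.times, s.temps).slope for s in seg.segments]
        for measured, printed in zip(slopes, mt.REFERENCE_NET_SLOPES):
            assert measured == pytest.approx(printed, rel=0.02)
        ep42 = [e for e in trace.metadata["stages"] if e["setpoint"] == 42.0][0]
        duty = mt.duty_cycle(relay, (ep42["dwell_start"] + 2.0, ep42["stage_end"]))
        assert duty.on_fraction == pytest.approx(mt.REFERENCE_DUTY, rel=0.02)


class TestBangBangLaw:
    @pytest.mark.parametrize("pair_seed", range(5))
    def test_plateau_on_fraction_equals_loss_over_gross(self, pair_seed):
        """For random (h, L0) the simulated plateau on-fraction equals the
        analytic bang-bang value L0/h within 2 % (cycle-aligned window)."""
        rng = np.random.default_rng(1000 + pair_seed)
        h = float(rng.uniform(0.3, 1.2))
        loss = float(rng.uniform(0.1, 0.5)) * h
        params = mt.PlantParams(heat_rates=((30.0, math.inf, h),), loss_rate=loss)
        sensor = mt.SensorSpec(noise_sd=0.0)
        ctrl = mt.ControllerConfig(stages=((42.0, 40.0),))
        proto = mt.ProtocolSpec(initial_T1=41.5, seed=0)
        trace, relay = mt.run_experiment(proto, params, sensor, ctrl)
        ep = trace.metadata["stages"][0]
        on_times = relay.times[relay.states]
        aligned = on_times[(on_times >= ep["dwell_start"] + 2.0) & (on_times <= ep["stage_end"])]
        assert len(aligned) >= 3
        report = mt.duty_cycle(relay, (aligned[0], aligned[-1]))
        assert report.on_fraction == pytest.approx(loss / h, rel=0.02)
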