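"""Surrogate-signal generation, cycle detection and phase assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fourdct.errors import InsufficientCyclesError, InvalidParameterError
from fourdct.respsignal import (
    GatingConfig,
    TriggerMode,
    assign_phases,
    detect_cycles,
    generate_irregular,
    generate_sinusoid,
    summarize_trace,
)


class TestSinusoid:
    @pytest.mark.parametrize("amplitude_mm, vmax_mm_s", [(10.0, 15.7), (20.0, 31.4)])
    def test_peak_velocity(self, amplitude_mm, vmax_mm_s):
        """Peak |velocity| of A*cos(2*pi*t/T) is 2*pi*A/T (1.57 / 3.14 cm/s
        for the normal / rapid patterns)."""
        trace = generate_sinusoid(amplitude_mm, 4.0, 20.0, sample_rate_hz=200.0)
        v = np.max(np.abs(np.gradient(trace.amplitude, trace.times)))
        assert v == pytest.approx(vmax_mm_s, rel=0.01)

    def test_zero_amplitude_is_constant(self):
        trace = generate_sinusoid(0.0, 4.0, 10.0)
        assert np.all(trace.amplitude == 0.0)

    def test_peak_at_time_zero(self):
        trace = generate_sinusoid(10.0, 4.0, 10.0)
        assert trace.amplitude[0] == pytest.approx(10.0)
        assert np.max(trace.amplitude) == pytest.approx(10.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(amplitude_mm=-1.0, period_s=4.0, duration_s=10.0),
            dict(amplitude_mm=10.0, period_s=0.0, duration_s=10.0),
            dict(amplitude_mm=10.0, period_s=4.0, duration_s=6.0),  # < 2 periods
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            generate_sinusoid(**kwargs)


class TestIrregular:
    def test_zero_irregularity_degenerates_to_sinusoid(self):
        irr = generate_irregular(10.0, 4.0, 0.0, 20.0, seed=0)
        sin = generate_sinusoid(10.0, 4.0, 20.0)
        np.testing.assert_allclose(irr.amplitude, sin.amplitude, atol=1e-12)
        summary = summarize_trace(detect_cycles(irr))
        assert summary.irregularity_pct < 0.5

    def test_seed_determinism(self):
        a = generate_irregular(10.0, 4.0, 15.0, 60.0, seed=7)
        b = generate_irregular(10.0, 4.0, 15.0, 60.0, seed=7)
        np.testing.assert_array_equal(a.amplitude, b.amplitude)
        c = generate_irregular(10.0, 4.0, 15.0, 60.0, seed=8)
        assert not np.array_equal(a.amplitude, c.amplitude)

    @pytest.mark.parametrize("target_pct", [5.0, 10.0, 15.0])
    def test_irregularity_recovery(self, target_pct):
        """Requested irregularity is recovered within +/-2 percentage points
        over >= 30 cycles, averaged over 5 seeds (parameter-recovery oracle:
        the generator draws period/amplitude at the stated CV)."""
        measured = []
        for seed in range(5):
            trace = generate_irregular(10.0, 4.0, target_pct, 140.0, seed=seed)
            features = detect_cycles(trace)
            assert len(features.cycle_periods) >= 30
            measured.append(summarize_trace(features).irregularity_pct)
        assert np.mean(measured) == pytest.approx(target_pct, abs=2.0)

    def test_invalid_irregularity(self):
        with pytest.raises(InvalidParameterError):
            generate_irregular(10.0, 4.0, 60.0, 30.0, seed=0)


class TestCycleDetection:
    def test_sinusoid_periods_and_amplitudes(self):
        trace = generate_sinusoid(10.0, 4.0, 20.0)
        f = detect_cycles(trace)
        np.testing.assert_allclose(f.cycle_periods, 4.0, atol=1.0 / trace.sample_rate)
        np.testing.assert_allclose(f.cycle_amplitudes, 20.0, rtol=0.02)
        assert len(f.cycle_periods) == len(f.peak_times) - 1

    def test_flat_trace_raises(self):
        with pytest.raises(InsufficientCyclesError):
            detect_cycles(generate_sinusoid(0.0, 4.0, 10.0))

    def test_deterministic_on_irregular(self):
        trace = generate_irregular(10.0, 4.0, 15.0, 60.0, seed=3)
        f1, f2 = detect_cycles(trace), detect_cycles(trace)
        np.testing.assert_array_equal(f1.peak_times, f2.peak_times)


class TestSummary:
    def test_pure_sinusoid(self):
        s = summarize_trace(detect_cycles(generate_sinusoid(10.0, 4.0, 30.0)))
        assert s.mean_period == pytest.approx(4.0, abs=0.05)
        assert s.mean_amplitude == pytest.approx(10.0, rel=0.02)  # zero-to-peak
        assert s.irregularity_pct == pytest.approx(0.0, abs=1e-6)

    def test_constant_cycles_have_zero_irregularity(self):
        from fourdct.respsignal import CycleFeatures

        f = CycleFeatures(
            peak_times=np.array([0.0, 4.0, 8.0, 12.0]),
            cycle_periods=np.array([4.0, 4.0, 4.0]),
            cycle_amplitudes=np.array([10.0, 10.0, 10.0]),
        )
        s = summarize_trace(f)
        assert s.irregularity_pct == 0.0
        assert s.mean_amplitude == pytest.approx(5.0)  # half of peak-to-trough

    def test_single_cycle_raises(self):
        from fourdct.respsignal import CycleFeatures

        f = CycleFeatures(
            peak_times=np.array([0.0, 4.0]),
            cycle_periods=np.array([4.0]),
            cycle_amplitudes=np.array([20.0]),
        )
        with pytest.raises(InsufficientCyclesError):
            summarize_trace(f)


class TestPhaseAssignment:
    def test_peak_gating_quarter_cycle(self, normal_trace, gating):
        """A sample one quarter period after a peak is at 25% phase (bin 2) —
        the peak-velocity neighbourhood."""
        pa = assign_phases(normal_trace, gating)
        i = int(np.argmin(np.abs(normal_trace.times - 5.0)))  # peak at 4 s + T/4
        assert pa.phase_pct[i] == pytest.approx(25.0, abs=0.5)
        assert pa.bin_index[i] == 2

    def test_peak_gating_at_peak(self, normal_trace, gating):
        pa = assign_phases(normal_trace, gating)
        i = int(np.argmin(np.abs(normal_trace.times - 8.0)))  # a detected peak
        assert pa.phase_pct[i] == pytest.approx(0.0, abs=0.5)
        assert pa.bin_index[i] == 0

    def test_samples_outside_triggers_flagged(self, normal_trace, gating):
        pa = assign_phases(normal_trace, gating)
        assert not pa.assigned[0]  # before the first detected peak
        assert np.all(pa.bin_index[~pa.assigned] == -1)
        assert np.all(np.isnan(pa.phase_pct[~pa.assigned]))

    def test_point_to_point_offset_matches_analytic_crossing(self, normal_trace):
        """For a sinusoid, the rising crossing of trough + 0.8*(peak-trough)
        leads the peak by arccos(2*0.8-1)/(2*pi) of a cycle, shifting all
        phase labels by 10-20% relative to peak gating."""
        peak = assign_phases(normal_trace, GatingConfig())
        p2p = assign_phases(
            normal_trace, GatingConfig(trigger_mode=TriggerMode.POINT_TO_POINT)
        )
        both = peak.assigned & p2p.assigned
        offset = np.mean((p2p.phase_pct[both] - peak.phase_pct[both]) % 100.0)
        analytic = np.degrees(np.arccos(2 * 0.8 - 1)) / 360.0 * 100.0
        assert offset == pytest.approx(analytic, abs=0.5)
        assert 10.0 <= offset <= 20.0

    def test_bin_floor_invariant_and_coverage(self, normal_trace, gating):
        pa = assign_phases(normal_trace, gating)
        ok = pa.assigned
        np.testing.assert_array_equal(
            pa.bin_index[ok], np.floor(pa.phase_pct[ok] / 10.0).astype(int)
        )
        # sample_rate * period = 100 >= 10 * n_bins: every bin hit each cycle
        t = normal_trace.times
        one_cycle = ok & (t >= 4.0) & (t < 8.0)
        assert set(pa.bin_index[one_cycle]) == set(range(10))

    def test_phase_monotone_between_triggers(self, normal_trace, gating):
        pa = assign_phases(normal_trace, gating)
        ok = pa.assigned
        d = np.diff(pa.phase_pct[ok]) % 100.0
        # phase advances (wrapping once per cycle) and never runs backwards
        assert np.all((d > 0) | np.isclose(d, 0.0))


@settings(max_examples=25, deadline=None)
@given(
    period=st.floats(2.0, 6.0),
    amplitude=st.floats(2.0, 20.0),
)
def test_sinusoid_parameter_recovery(period, amplitude):
    """summarize(detect(generate_sinusoid)) recovers (T, A) within 2%."""
    trace = generate_sinusoid(amplitude, period, 6 * period, sample_rate_hz=50.0)
    s = summarize_trace(detect_cycles(trace))
    assert s.mean_period == pytest.approx(period, rel=0.02)
    assert s.mean_amplitude == pytest.approx(amplitude, rel=0.02)
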