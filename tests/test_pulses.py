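import numpy as np
import pytest

from phantomflow.errors import AlignmentError, DataError, ProtocolError, SegmentationError
from phantomflow.phantom import DEFAULT_PHANTOM, simulate_phantom
from phantomflow.pulses import (
    PressureTrace,
    compare_methods,
    delta_p,
    extrema,
    representative_curve,
    segment_pulses,
    timing_shift,
)
from phantomflow.units import pa_to_mmhg

PERIOD = 1.7
DT = 1e-3


def periodic_trace(n_pulses=6, shift=0.0, label="p"):
    """Six identical periods of a bump signal, mmHg."""
    t = np.arange(round(n_pulses * PERIOD / DT)) * DT
    phase = np.mod(t - shift, PERIOD)
    p = np.where(phase < 0.2, np.sin(np.pi * phase / 0.2) ** 2 * 5.0, 0.0)
    return PressureTrace(time=t, pressure=p, label=label)


class TestSegmentation:
    def test_six_identical_periods(self):
        tr = periodic_trace()
        ens = segment_pulses(tr, PERIOD)
        assert ens.n_pulses == 6
        assert np.allclose(ens.segments - ens.segments[0], 0.0)

    def test_threshold_trigger_finds_shifted_starts(self):
        tr = periodic_trace(shift=0.3)
        ens = segment_pulses(tr, PERIOD, trigger=2.5)
        # Upward crossings of 2.5 mmHg occur a fixed offset into each pulse.
        starts_t = tr.time[ens.starts]
        gaps = np.diff(starts_t)
        assert np.allclose(gaps, PERIOD, atol=2 * DT)

    def test_constant_trace_fails_segmentation(self):
        t = np.arange(round(4 * PERIOD / DT)) * DT
        tr = PressureTrace(time=t, pressure=np.full_like(t, 3.0))
        with pytest.raises(SegmentationError):
            segment_pulses(tr, PERIOD, trigger=5.0)

    def test_short_trace_rejected(self):
        t = np.arange(round(1.2 * PERIOD / DT)) * DT
        with pytest.raises(DataError):
            segment_pulses(PressureTrace(time=t, pressure=np.zeros_like(t)), PERIOD)


class TestRepresentativeCurve:
    def test_identical_pulses_reproduce_single_pulse(self):
        ens = segment_pulses(periodic_trace(), PERIOD)
        rep = representative_curve(ens)
        assert np.allclose(rep.pressure, ens.segments[0])

    def test_mean_of_pulses_four_to_six(self):
        tr = periodic_trace()
        n = round(PERIOD / DT)
        # Plant distinct known curves in pulses 4-6.
        for k, scale in zip(range(3, 6), (1.0, 2.0, 3.0)):
            tr.pressure[k * n : (k + 1) * n] = scale
        ens = segment_pulses(tr, PERIOD)
        rep = representative_curve(ens, discard=3, use=3)
        assert np.allclose(rep.pressure, 2.0)

    def test_discard_zero_use_all_is_plain_mean(self):
        ens = segment_pulses(periodic_trace(), PERIOD)
        rep = representative_curve(ens, discard=0, use=6)
        assert np.allclose(rep.pressure, ens.segments.mean(axis=0))

    def test_too_few_pulses_is_protocol_error(self):
        ens = segment_pulses(periodic_trace(n_pulses=4), PERIOD)
        with pytest.raises(ProtocolError, match="4"):
            representative_curve(ens, discard=3, use=3)

    def test_constant_offset_invariance(self):
        ens = segment_pulses(periodic_trace(), PERIOD)
        rep1 = representative_curve(ens)
        ens.segments = ens.segments + 7.5
        rep2 = representative_curve(ens)
        assert np.allclose(rep2.pressure - rep1.pressure, 7.5)


class TestDeltaP:
    def test_identical_traces_zero(self):
        tr = periodic_trace()
        assert np.allclose(delta_p(tr, tr).pressure, 0.0)

    def test_constant_offset(self):
        tr = periodic_trace()
        lower = PressureTrace(time=tr.time, pressure=tr.pressure - 2.0)
        assert np.allclose(delta_p(tr, lower).pressure, 2.0)

    def test_antisymmetry(self):
        a = periodic_trace()
        b = periodic_trace(shift=0.1)
        assert np.allclose(delta_p(a, b).pressure, -delta_p(b, a).pressure)

    def test_offset_beyond_one_sample_rejected(self):
        a = periodic_trace()
        b = PressureTrace(time=a.time + 5 * DT, pressure=a.pressure)
        with pytest.raises(AlignmentError):
            delta_p(a, b)

    def test_phantom_simulation_shape(self, waveform):
        """The simulated loop's dP curve rises then undershoots below zero."""
        res = simulate_phantom(DEFAULT_PHANTOM, waveform, n_pulses=6, dt=DT)
        inlet = PressureTrace(time=res.time, pressure=pa_to_mmhg(res.p_in), label="inlet")
        outlet = PressureTrace(time=res.time, pressure=pa_to_mmhg(res.p_out), label="outlet")
        dp = delta_p(inlet, outlet)
        rep = representative_curve(segment_pulses(dp, waveform.period), discard=3, use=3)
        mx, tmx, mn, tmn = extrema(rep)
        assert mx > 0 > mn
        assert tmx < tmn


class TestExtrema:
    def test_half_sine_pulse(self):
        t = np.linspace(0, 1, 101)
        curve = PressureTrace(time=t, pressure=np.sin(2 * np.pi * t))
        mx, tmx, mn, tmn = extrema(curve)
        assert mx == pytest.approx(1.0, abs=1e-3)
        assert tmx == pytest.approx(0.25, abs=0.01)
        assert mn == pytest.approx(-1.0, abs=1e-3)
        assert tmn == pytest.approx(0.75, abs=0.01)

    def test_tie_breaks_to_earlier_time(self):
        t = np.linspace(0, 1, 11)
        p = np.zeros_like(t)
        p[[2, 7]] = 4.0
        _, tmx, _, _ = extrema(PressureTrace(time=t, pressure=p))
        assert tmx == pytest.approx(t[2])

    def test_planted_values_recovered(self):
        t = np.linspace(0, 1.7, 1701)
        p = np.zeros_like(t)
        p[400] = 6.25
        p[900] = -3.5
        mx, tmx, mn, tmn = extrema(PressureTrace(time=t, pressure=p))
        assert (mx, tmx, mn, tmn) == (6.25, pytest.approx(0.4), -3.5, pytest.approx(0.9))


class TestTimingShift:
    def test_identical_curves_zero_lag(self):
        tr = periodic_trace(n_pulses=2)
        assert timing_shift(tr, tr) == pytest.approx(0.0, abs=1e-9)

    def test_planted_shift_recovered(self):
        a = periodic_trace(n_pulses=2)
        b = periodic_trace(n_pulses=2, shift=0.13)
        assert timing_shift(a, b) == pytest.approx(0.13, abs=DT)

    def test_sign_convention_b_lags_a_positive(self):
        a = periodic_trace(n_pulses=2)
        b = periodic_trace(n_pulses=2, shift=0.05)
        assert timing_shift(a, b) > 0
        assert timing_shift(b, a) < 0

    def test_zero_variance_rejected(self):
        t = np.linspace(0, 2, 21)
        flat = PressureTrace(time=t, pressure=np.ones_like(t))
        with pytest.raises(DataError):
            timing_shift(flat, flat)


class TestCompareMethods:
    def test_identical_groups_p_near_one(self):
        groups = {"direct": [(2.0, -3.0), (2.0, -3.0), (2.1, -3.1)], "bsi": [(2.0, -3.0), (2.0, -3.0), (2.1, -3.1)]}
        s = compare_methods(groups)
        assert np.all(s.pairwise["p_value"] > 0.99)
        assert not s.pairwise["significant"].any()

    def test_widely_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        g1 = [(v, -v) for v in rng.normal(2.0, 0.1, 4)]
        g2 = [(v, -v) for v in rng.normal(12.0, 0.1, 4)]
        s = compare_methods({"a": g1, "b": g2})
        assert np.all(s.pairwise["p_value"] < 0.05)
        assert s.pairwise["significant"].all()
        assert s.anova["max_dp"] < 0.05

    def test_single_replicate_skipped_with_note(self):
        s = compare_methods({"a": [(2.0, -3.0)], "b": [(2.1, -3.0), (2.2, -3.2)]})
        assert np.isnan(s.table.loc["a", "max_dp_sd"])
        assert any("single replicate" in n for n in s.notes)
        assert len(s.pairwise) == 0
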