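"""Synthetic boundary waveforms and wall-traction fixtures."""

import numpy as np
import pytest

from stenoflow.indices import osi
from stenoflow.waveforms import (
    MMHG_PA,
    PeriodicWaveform,
    WaveformSpec,
    inlet_velocity_waveform,
    outlet_pressure_waveform,
    synthetic_wall_traction,
)


@pytest.fixture
def spec():
    return WaveformSpec()


class TestInletVelocity:
    def test_period_from_heart_rate(self, spec):
        w = inlet_velocity_waveform(spec)
        assert w.period == pytest.approx(60.0 / 70.0, rel=1e-12)

    def test_exact_periodicity(self, spec):
        w = inlet_velocity_waveform(spec)
        t = np.linspace(0.0, w.period, 37)
        assert np.allclose(w(t + w.period), w(t), atol=1e-14)

    def test_peak_and_nonnegative_without_notch(self):
        w = inlet_velocity_waveform(WaveformSpec(peak_velocity=1.0, reverse_fraction=0.0))
        _, v = w.sample(4000)
        assert v.min() >= 0.0
        assert v.max() == pytest.approx(1.0, rel=1e-6)

    def test_notch_depth_and_positive_mean(self, spec):
        w = inlet_velocity_waveform(spec)
        _, v = w.sample(4000)
        assert v.min() == pytest.approx(-spec.reverse_fraction * spec.peak_velocity,
                                        rel=1e-6)
        assert w.mean() > 0.0

    def test_quadrature_consistency_under_doubling(self, spec):
        w = inlet_velocity_waveform(spec)
        m1 = np.mean(w.sample(500)[1])
        m2 = np.mean(w.sample(1000)[1])
        assert abs(m2 - m1) < 1e-3 * abs(m2)


class TestOutletPressure:
    def test_extrema_match_spec(self, spec):
        w = outlet_pressure_waveform(spec)
        _, p = w.sample(8000)
        assert p.max() == pytest.approx(120.0 * MMHG_PA, rel=1e-6)
        assert p.min() == pytest.approx(80.0 * MMHG_PA, rel=1e-9)

    def test_mean_strictly_between_extrema(self, spec):
        w = outlet_pressure_waveform(spec)
        m = w.mean() / MMHG_PA
        assert 80.0 < m < 120.0

    def test_periodic_closure_and_smoothness(self, spec):
        w = outlet_pressure_waveform(spec)
        assert w(0.0) == pytest.approx(w(w.period), abs=1e-10)
        # first derivative continuous across the seam: the jump must be
        # negligible against the waveform's characteristic slope
        h = 1e-6
        dl = (w(w.period) - w(w.period - h)) / h
        dr = (w(h) - w(0.0)) / h
        t, p = w.sample(4000)
        slope_scale = np.max(np.abs(np.diff(p))) / (w.period / 4000)
        assert abs(dr - dl) < 1e-3 * slope_scale

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError, match="systolic"):
            WaveformSpec(systolic_pressure=70.0, diastolic_pressure=80.0)


class TestCsvRoundTrip:
    def test_waveform_round_trip(self, spec, tmp_path):
        w = outlet_pressure_waveform(spec)
        path = tmp_path / "wave.csv"
        w.to_csv(path, n=400)
        w2 = PeriodicWaveform.from_csv(path)
        assert w2.period == pytest.approx(w.period, rel=1e-9)
        t = np.linspace(0.0, w.period, 101)
        assert np.allclose(w2(t), w(t), rtol=1e-4, atol=1e-2)


class TestSyntheticTraction:
    @pytest.mark.parametrize("pattern,expected_osi", [
        ("constant", 0.0),
        ("reversing", 0.5),
        ("rotating", 0.5),
    ])
    def test_pattern_osi_identities(self, pattern, expected_osi):
        series = synthetic_wall_traction(pattern, amplitude=2.3, n_points=6, n_time=100)
        assert np.allclose(osi(series), expected_osi, atol=1e-12)

    def test_offset_sine_keeps_direction(self):
        # amplitude < mean: the traction never changes sign, so OSI = 0
        series = synthetic_wall_traction("offset_sine", amplitude=1.0, n_points=4,
                                         n_time=128, offset=2.5)
        assert np.all(series.tau[:, :, 0] > 0.0)
        assert np.allclose(osi(series), 0.0, atol=1e-12)

    def test_uniform_sampling_contract(self):
        series = synthetic_wall_traction("constant", n_points=3, n_time=50, period=0.8)
        assert series.times.size == 50
        dt = np.diff(series.times)
        assert np.allclose(dt, 0.8 / 50)
        assert series.times[0] == 0.0  # endpoint excluded at the far end

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            synthetic_wall_traction("sawtooth")

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            synthetic_wall_traction("constant", n_time=3)
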