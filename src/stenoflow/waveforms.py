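"""Synthetic pulsatile boundary waveforms and wall-traction fixtures.

The clinical boundary conditions of interest — an inlet velocity waveform
with a single systolic peak and a brief post-systolic reverse-flow notch,
and outlet pressure waveforms spanning a diastolic/systolic range — exist
in practice only as recorded figures.  This module generates parametric
shape emulations of them: piecewise-smooth closed forms whose amplitudes
and timings are free parameters of :class:`WaveformSpec`, exactly periodic
in the cardiac period T = 60/heart-rate.

It also generates small analytic wall-traction series (constant, reversing,
offset sine, rotating) used to exercise the TAWSS/OSI/RRT chain without
running the flow solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .indices import WallTractionSeries

__all__ = [
    "MMHG_PA",
    "PeriodicWaveform",
    "WaveformSpec",
    "inlet_velocity_waveform",
    "outlet_pressure_waveform",
    "synthetic_wall_traction",
]

#: One millimetre of mercury in pascal.
MMHG_PA = 133.322


@dataclass
class PeriodicWaveform:
    """One cardiac cycle of a boundary quantity, exactly periodic.

    Evaluation maps any time onto the base cycle: ``w(t) = w(t mod period)``.
    The waveform is backed either by an analytic closed form (``fn``) or by
    uniformly spread samples with periodic linear interpolation.
    """

    period: float
    fn: Callable[[np.ndarray], np.ndarray] | None = None
    sample_times: np.ndarray | None = None
    sample_values: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.period <= 0.0:
            raise ValueError(f"period must be > 0, got {self.period}")
        if self.fn is None and self.sample_values is None:
            raise ValueError("provide either fn or samples")

    @classmethod
    def from_samples(cls, times, values, period: float, units: str = "") -> "PeriodicWaveform":
        """Build from (time, value) samples inside [0, period)."""
        t = np.asarray(times, dtype=float)
        v = np.asarray(values, dtype=float)
        order = np.argsort(t)
        return cls(period=period, sample_times=t[order], sample_values=v[order], units=units)

    def __call__(self, t):
        tau = np.mod(np.asarray(t, dtype=float), self.period)
        if self.fn is not None:
            out = self.fn(tau)
        else:
            # periodic linear interpolation: wrap one sample on each side
            ts = np.concatenate(
                ([self.sample_times[-1] - self.period], self.sample_times,
                 [self.sample_times[0] + self.period])
            )
            vs = np.concatenate(
                ([self.sample_values[-1]], self.sample_values, [self.sample_values[0]])
            )
            out = np.interp(tau, ts, vs)
        if np.ndim(t) == 0:
            return float(out)
        return out

    def sample(self, n: int):
        """n uniform samples over [0, period), endpoint excluded."""
        t = np.arange(n) * (self.period / n)
        return t, self(t)

    def mean(self, n: int = 2000) -> float:
        """Cycle mean by uniform periodic quadrature."""
        _, v = self.sample(n)
        return float(np.mean(v))

    def to_csv(self, path, n: int = 200) -> None:
        t, v = self.sample(n)
        df = pd.DataFrame({"time_s": t, f"value_{self.units or 'SI'}": v})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PeriodicWaveform":
        df = pd.read_csv(path)
        tcol = df.columns[0]
        vcol = df.columns[1]
        units = vcol.split("value_", 1)[-1]
        t = df[tcol].to_numpy(dtype=float)
        # samples exclude the period endpoint; recover T from uniform spacing
        dt = t[1] - t[0]
        return cls.from_samples(t, df[vcol].to_numpy(dtype=float),
                                period=float(t[-1] + dt), units=units)


@dataclass(frozen=True)
class WaveformSpec:
    """Shape parameters of the synthetic cardiac-cycle waveforms.

    heart_rate is in beats per minute (default 70); peak_velocity in m/s is
    the maximum of the cycle's cross-section-mean inlet velocity;
    reverse_fraction scales the depth of the post-systolic backflow notch;
    pressures are in mmHg (clinical convention; converted to Pa internally);
    systolic_time_fraction is the fraction of the cycle occupied by the
    systolic ejection phase.
    """

    heart_rate: float = 70.0
    peak_velocity: float = 0.5
    reverse_fraction: float = 0.15
    systolic_pressure: float = 120.0
    diastolic_pressure: float = 80.0
    systolic_time_fraction: float = 0.35
    notch_time_fraction: float = 0.10
    pressure_skew: float = 0.4

    def __post_init__(self) -> None:
        if self.heart_rate <= 0.0:
            raise ValueError(f"heart_rate must be > 0, got {self.heart_rate}")
        if not (0.0 <= self.reverse_fraction < 1.0):
            raise ValueError(
                f"reverse_fraction must be in [0, 1), got {self.reverse_fraction}"
            )
        if self.systolic_pressure <= self.diastolic_pressure:
            raise ValueError(
                "systolic_pressure must exceed diastolic_pressure, got "
                f"{self.systolic_pressure} <= {self.diastolic_pressure}"
            )
        if not (0.0 < self.systolic_time_fraction < 1.0):
            raise ValueError("systolic_time_fraction must be in (0, 1)")
        if not (0.0 < self.notch_time_fraction < 1.0 - self.systolic_time_fraction):
            raise ValueError("notch_time_fraction must fit in the diastolic interval")
        if not (0.0 <= self.pressure_skew < 1.0):
            raise ValueError("pressure_skew must be in [0, 1)")

    @property
    def period(self) -> float:
        """Cardiac period T = 60 / heart_rate, s."""
        return 60.0 / self.heart_rate


def inlet_velocity_waveform(spec: WaveformSpec) -> PeriodicWaveform:
    """Cross-section-mean inlet velocity over one cardiac cycle, m/s.

    A sin²-shaped systolic ejection pulse of height ``peak_velocity`` over
    the first ``systolic_time_fraction`` of the cycle, followed by a brief
    sin²-shaped reverse-flow notch of depth ``reverse_fraction × peak``;
    zero during the remainder of diastole.  C¹-smooth and exactly periodic;
    the cycle mean is positive for any valid spec.
    """
    T = spec.period
    t_s = spec.systolic_time_fraction * T
    t_n = spec.notch_time_fraction * T
    vp = spec.peak_velocity
    rf = spec.reverse_fraction

    def fn(tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        v = np.zeros_like(tau)
        sys_mask = tau < t_s
        v[sys_mask] = vp * np.sin(np.pi * tau[sys_mask] / t_s) ** 2
        notch = (tau >= t_s) & (tau < t_s + t_n)
        v[notch] = -rf * vp * np.sin(np.pi * (tau[notch] - t_s) / t_n) ** 2
        return v

    return PeriodicWaveform(period=T, fn=fn, units="m_per_s")


def outlet_pressure_waveform(spec: WaveformSpec) -> PeriodicWaveform:
    """Outlet pressure over one cardiac cycle, Pa.

    A raised-cosine pulse through a smooth monotone time warp
    g(t) = t/T + (skew/2π)(1 − cos 2πt/T), which skews the systolic peak
    early while keeping the waveform C¹ across the periodic seam.  The
    cycle maximum equals the systolic and the minimum the diastolic
    pressure exactly (inputs in mmHg, output in Pa).
    """
    T = spec.period
    p_sys = spec.systolic_pressure * MMHG_PA
    p_dia = spec.diastolic_pressure * MMHG_PA
    beta = spec.pressure_skew

    def fn(tau: np.ndarray) -> np.ndarray:
        x = np.asarray(tau, dtype=float) / T
        g = x + beta / (2.0 * np.pi) * (1.0 - np.cos(2.0 * np.pi * x))
        s = 0.5 * (1.0 - np.cos(2.0 * np.pi * g))
        return p_dia + (p_sys - p_dia) * s

    return PeriodicWaveform(period=T, fn=fn, units="Pa")


_PATTERNS = ("constant", "reversing", "offset_sine", "rotating")


def synthetic_wall_traction(
    pattern: str,
    amplitude: float = 1.0,
    n_points: int = 8,
    n_time: int = 100,
    period: float = 60.0 / 70.0,
    offset: float | None = None,
) -> WallTractionSeries:
    """Analytic wall-traction fixtures for the index chain.

    Patterns (uniform sampling over one period, endpoint excluded):

    - ``constant``: fixed vector of magnitude ``amplitude`` → OSI = 0.
    - ``reversing``: zero-mean sinusoid of amplitude ``amplitude`` along one
      tangent direction → OSI = 0.5.
    - ``offset_sine``: mean ``offset`` (default 2×amplitude) plus a sinusoid
      of amplitude ``amplitude`` in one direction; never changes sign when
      ``amplitude < offset``, so OSI = 0.
    - ``rotating``: vector of constant magnitude rotating uniformly in the
      tangent plane; its time integral vanishes, so OSI = 0.5.
    """
    if pattern not in _PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {_PATTERNS}")
    if n_time < 4:
        raise ValueError(f"need n_time >= 4, got {n_time}")
    if n_points < 1:
        raise ValueError(f"need n_points >= 1, got {n_points}")

    times = np.arange(n_time) * (period / n_time)
    phase = 2.0 * np.pi * times / period
    positions = np.linspace(0.0, 0.01, n_points)  # arc length, m
    tau = np.zeros((n_points, n_time, 2))
    if pattern == "constant":
        tau[:, :, 0] = amplitude
    elif pattern == "reversing":
        tau[:, :, 0] = amplitude * np.sin(phase)[None, :]
    elif pattern == "offset_sine":
        m = 2.0 * amplitude if offset is None else offset
        tau[:, :, 0] = m + amplitude * np.sin(phase)[None, :]
    elif pattern == "rotating":
        tau[:, :, 0] = amplitude * np.cos(phase)[None, :]
        tau[:, :, 1] = amplitude * np.sin(phase)[None, :]
    return WallTractionSeries(positions=positions, times=times, period=period, tau=tau)
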