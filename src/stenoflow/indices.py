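"""Wall-shear-derived hemodynamic indices: TAWSS, OSI, RRT.

Given the time-resolved wall-shear-stress (WSS) vector τ⃗_w(s, t) at wall
sample points over one cardiac cycle of period T, the chain computes

    TAWSS(s) = (1/T) ∫₀ᵀ |τ⃗_w| dt                       [Pa]
    OSI(s)   = ½ (1 − |∫₀ᵀ τ⃗_w dt| / ∫₀ᵀ |τ⃗_w| dt)      [-], in [0, 0.5]
    RRT(s)   = 1 / ((1 − 2·OSI) · TAWSS)                 [Pa⁻¹]

OSI is 0 for a direction-constant WSS vector and 0.5 for a purely
oscillatory (zero time-mean) one.  RRT, a proxy for the residence time of
blood elements near the wall, is singular where OSI → 0.5 or TAWSS → 0;
such positions are flagged and reported as a capped value rather than an
unbounded float so tabular outputs stay finite.

Quadrature is the composite trapezoid with periodic closure: on a uniform
time grid t_k = kT/N (endpoint excluded) this reduces to (T/N)·Σ f_k, which
is spectrally accurate for smooth periodic integrands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WallTractionSeries",
    "IndexProfile",
    "tawss",
    "osi",
    "rrt",
    "index_profile",
]


@dataclass
class WallTractionSeries:
    """Time-resolved WSS vectors at wall sample points over one period.

    Attributes
    ----------
    positions : (n_pos,) float array
        Wall sample positions (arc length along the wall), m; strictly
        increasing.
    times : (n_time,) float array
        Uniform time samples covering [0, period), endpoint excluded, s.
    period : float
        Cycle period T, s.
    tau : (n_pos, n_time, n_comp) float array
        Traction vector components in the local wall tangent plane, Pa;
        n_comp is 2 or 3.
    """

    positions: np.ndarray
    times: np.ndarray
    period: float
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.times.size < 4:
            raise ValueError(f"need at least 4 time samples, got {self.times.size}")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
            raise ValueError("time samples must be uniformly spaced")
        if np.any(np.diff(self.positions) <= 0.0):
            raise ValueError("positions must be strictly increasing")
        if self.tau.shape[:2] != (self.positions.size, self.times.size):
            raise ValueError(
                f"tau shape {self.tau.shape} inconsistent with "
                f"{self.positions.size} positions x {self.times.size} times"
            )
        if self.tau.shape[2] not in (2, 3):
            raise ValueError("tau must carry 2 or 3 vector components")
        if self.period <= 0.0:
            raise ValueError("period must be positive")

    @property
    def n_positions(self) -> int:
        return self.positions.size

    def scaled(self, k: float) -> "WallTractionSeries":
        """Series with all traction vectors multiplied by k."""
        return WallTractionSeries(self.positions, self.times, self.period, k * self.tau)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: position_m, time_s, tau_t1_Pa, tau_t2_Pa[, tau_t3_Pa]."""
        n_pos, n_t, n_c = self.tau.shape
        cols = {
            "position_m": np.repeat(self.positions, n_t),
            "time_s": np.tile(self.times, n_pos),
        }
        for c in range(n_c):
            cols[f"tau_t{c + 1}_Pa"] = self.tau[:, :, c].ravel()
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, period: float | None = None) -> "WallTractionSeries":
        comp_cols = [c for c in df.columns if c.startswith("tau_t")]
        positions = np.unique(df["position_m"].to_numpy(dtype=float))
        times = np.unique(df["time_s"].to_numpy(dtype=float))
        tau = np.empty((positions.size, times.size, len(comp_cols)))
        piv = df.sort_values(["position_m", "time_s"])
        for c, col in enumerate(comp_cols):
            tau[:, :, c] = piv[col].to_numpy(dtype=float).reshape(positions.size, times.size)
        if period is None:
            dt = times[1] - times[0]
            period = float(times[-1] + dt)
        return cls(positions=positions, times=times, period=period, tau=tau)

    @classmethod
    def from_csv(cls, path, period: float | None = None) -> "WallTractionSeries":
        return cls.from_frame(pd.read_csv(path), period=period)


@dataclass
class IndexProfile:
    """Per-wall-position hemodynamic indices with RRT singularity flags."""

    positions: np.ndarray
    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray
    rrt_flag: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_m": self.positions,
                "tawss_Pa": self.tawss,
                "osi": self.osi,
                "rrt_inv_Pa": self.rrt,
                "rrt_flag": self.rrt_flag.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _periodic_integral(values: np.ndarray, period: float, axis: int = 1) -> np.ndarray:
    """∫₀ᵀ f dt on a uniform periodic grid (trapezoid with wrap = mean·T)."""
    n = values.shape[axis]
    return np.sum(values, axis=axis) * (period / n)


def tawss(series: WallTractionSeries) -> np.ndarray:
    """Time-averaged WSS magnitude per wall position, Pa."""
    mag = np.linalg.norm(series.tau, axis=2)
    return _periodic_integral(mag, series.period) / series.period


def osi(series: WallTractionSeries) -> np.ndarray:
    """Oscillatory shear index per wall position, clamped to [0, 0.5].

    Positions where the WSS magnitude integral vanishes (no traction at
    all over the cycle) return 0 by convention.
    """
    vec_int = _periodic_integral(series.tau, series.period, axis=1)  # (n_pos, n_comp)
    mag_int = _periodic_integral(np.linalg.norm(series.tau, axis=2), series.period)
    out = np.zeros(series.n_positions)
    nz = mag_int > 0.0
    out[nz] = 0.5 * (1.0 - np.linalg.norm(vec_int[nz], axis=1) / mag_int[nz])
    return np.clip(out, 0.0, 0.5)


def rrt(
    osi_values: np.ndarray,
    tawss_values: np.ndarray,
    epsilon: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative residence time per position, Pa⁻¹, with singularity flags.

    RRT = 1 / ((1 − 2·OSI) · TAWSS).  Positions with (1 − 2·OSI) < epsilon
    are flagged and reported as the capped value 1/(epsilon·TAWSS);
    positions with TAWSS = 0 are flagged infinite.

    Returns
    -------
    (values, flags)
        values : (n_pos,) float array (capped where flagged, inf where
        TAWSS = 0); flags : (n_pos,) bool array.
    """
    if epsilon <= 0.0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    o = np.asarray(osi_values, dtype=float)
    t = np.asarray(tawss_values, dtype=float)
    if np.any((o < 0.0) | (o > 0.5)):
        raise ValueError("osi values must lie in [0, 0.5]")
    if np.any(t < 0.0):
        raise ValueError("tawss values must be nonnegative")
    denom_dir = 1.0 - 2.0 * o
    flags = (denom_dir < epsilon) | (t == 0.0)
    values = np.empty_like(t)
    ok = ~flags
    values[ok] = 1.0 / (denom_dir[ok] * t[ok])
    capped = flags & (t > 0.0)
    values[capped] = 1.0 / (epsilon * t[capped])
    values[flags & (t == 0.0)] = np.inf
    return values, flags


def index_profile(series: WallTractionSeries, epsilon: float = 1e-3) -> IndexProfile:
    """Compose TAWSS, OSI and RRT into a per-position profile."""
    t = tawss(series)
    o = osi(series)
    r, flags = rrt(o, t, epsilon=epsilon)
    return IndexProfile(positions=series.positions.copy(), tawss=t, osi=o,
                        rrt=r, rrt_flag=flags)
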