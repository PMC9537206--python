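"""Blood rheology: the Carreau-Yasuda shear-thinning viscosity law.

Whole blood is shear-thinning: at low shear rates rouleaux formation raises
the apparent viscosity toward a zero-shear plateau ``mu_zero``, while at high
shear rates the suspension disperses and the viscosity approaches the
infinite-shear plateau ``mu_inf``.  The Carreau-Yasuda law interpolates
between the two plateaus,

    mu(gamma_dot) = mu_inf + (mu_zero - mu_inf) /
                    (1 + (lambda * gamma_dot)**a) ** ((1 - n) / a),

with relaxation time ``lambda`` (s), power-law index ``n`` and Yasuda
transition exponent ``a``.  The default constants are a standard whole-blood
fit (mu_zero = 0.056 Pa.s, mu_inf = 0.0035 Pa.s, lambda = 3.313 s,
n = 0.3568); ``a`` defaults to 2, which reduces the law to the classic
Carreau blood model consistent with those constants.

The shear-rate argument is the frame-invariant magnitude of the rate-of-
deformation tensor D = (grad v + grad v^T)/2,

    gamma_dot = sqrt(2 D : D),

which reduces to the velocity gradient ``k`` in simple shear u(y) = k*y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CarreauYasudaParams",
    "BloodProperties",
    "NewtonianParams",
    "apparent_viscosity",
    "shear_rate_magnitude",
]


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Constants of the Carreau-Yasuda apparent-viscosity law.

    Parameters
    ----------
    mu_zero : float
        Zero-shear viscosity plateau, Pa·s.
    mu_inf : float
        Infinite-shear viscosity plateau, Pa·s.
    lambda_time : float
        Relaxation time constant λ, s.
    n_index : float
        Power-law index n (shear-thinning for n < 1), dimensionless.
    a_exponent : float
        Yasuda transition exponent a; a = 2 recovers the Carreau model.
    """

    mu_zero: float = 0.056
    mu_inf: float = 0.0035
    lambda_time: float = 3.313
    n_index: float = 0.3568
    a_exponent: float = 2.0

    def __post_init__(self) -> None:
        if not (self.mu_zero >= self.mu_inf > 0.0):
            raise ValueError(
                f"require mu_zero >= mu_inf > 0, got mu_zero={self.mu_zero}, "
                f"mu_inf={self.mu_inf}"
            )
        if self.lambda_time <= 0.0:
            raise ValueError(f"lambda_time must be > 0, got {self.lambda_time}")
        if not (0.0 < self.n_index <= 1.0):
            raise ValueError(f"n_index must be in (0, 1], got {self.n_index}")
        if self.a_exponent <= 0.0:
            raise ValueError(f"a_exponent must be > 0, got {self.a_exponent}")

    def viscosity(self, shear_rate):
        """Apparent viscosity at the given shear rate(s); see
        :func:`apparent_viscosity`."""
        return apparent_viscosity(self, shear_rate)


@dataclass(frozen=True)
class NewtonianParams:
    """Constant-viscosity marker used for validation oracles."""

    mu: float = 0.0035

    def __post_init__(self) -> None:
        if self.mu <= 0.0:
            raise ValueError(f"viscosity must be > 0, got {self.mu}")

    def viscosity(self, shear_rate):
        return np.broadcast_to(np.float64(self.mu), np.shape(shear_rate)).copy() \
            if np.ndim(shear_rate) else float(self.mu)


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties: density plus a rheology law.

    Density defaults to 1060 kg/m³ (whole blood).  ``rheology`` is either
    :class:`CarreauYasudaParams` or the :class:`NewtonianParams` constant-
    viscosity marker.
    """

    density: float = 1060.0
    rheology: CarreauYasudaParams | NewtonianParams = field(
        default_factory=CarreauYasudaParams
    )

    def __post_init__(self) -> None:
        if self.density <= 0.0:
            raise ValueError(f"density must be > 0, got {self.density}")

    def viscosity(self, shear_rate):
        return self.rheology.viscosity(shear_rate)


def apparent_viscosity(params: CarreauYasudaParams, shear_rate):
    """Carreau-Yasuda apparent viscosity, Pa·s.

    Parameters
    ----------
    params : CarreauYasudaParams
    shear_rate : float or ndarray
        Shear-rate magnitude γ̇ ≥ 0, s⁻¹ (the invariant sqrt(2 D:D)).

    Returns
    -------
    float or ndarray
        μ∞ + (μ₀ − μ∞) / (1 + (λ γ̇)^a)^((1−n)/a); lies in (μ∞, μ₀].

    Raises
    ------
    ValueError
        If any shear rate is negative (callers must pass the invariant
        magnitude, which is nonnegative by construction).
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0.0):
        raise ValueError("shear_rate must be nonnegative (pass the invariant magnitude)")
    p = params
    mu = p.mu_inf + (p.mu_zero - p.mu_inf) / (
        1.0 + (p.lambda_time * g) ** p.a_exponent
    ) ** ((1.0 - p.n_index) / p.a_exponent)
    if np.ndim(shear_rate) == 0:
        return float(mu)
    return mu


def shear_rate_magnitude(grad_v):
    """Frame-invariant shear-rate magnitude γ̇ = sqrt(2 D:D), s⁻¹.

    Parameters
    ----------
    grad_v : ndarray, shape (..., d, d) with d in {2, 3}
        Velocity-gradient tensor(s) G with G[i, j] = ∂v_i/∂x_j.  Leading
        batch dimensions are broadcast through.

    Returns
    -------
    float or ndarray
        Nonnegative scalar per tensor; invariant under rotations of the
        frame, zero for rigid rotation (antisymmetric G), and equal to k
        for simple shear ∂u/∂y = k.
    """
    g = np.asarray(grad_v, dtype=float)
    if g.ndim < 2 or g.shape[-1] != g.shape[-2] or g.shape[-1] not in (2, 3):
        raise ValueError(f"grad_v must have shape (..., d, d), d in {{2,3}}; got {g.shape}")
    if not np.all(np.isfinite(g)):
        raise ValueError("grad_v entries must be finite")
    d = 0.5 * (g + np.swapaxes(g, -1, -2))
    mag = np.sqrt(2.0 * np.sum(d * d, axis=(-1, -2)))
    if mag.ndim == 0:
        return float(mag)
    return mag
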