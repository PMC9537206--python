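"""Idealized axisymmetric stenosed-vessel geometry and its structured grid.

The vessel is a straight circular tube of inlet radius R0 carrying a smooth
axisymmetric area-reduction bump.  Severity S is defined as the *area*
reduction fraction at the throat: the throat cross-section equals
(1 - S) x the inlet cross-section exactly.  The wall radius is

    r(z) = R0 * sqrt(1 - S * b(z)),
    b(z) = 1/2 (1 + cos(2 pi (z - z_c)/L_s))   for |z - z_c| <= L_s/2,
    b(z) = 0                                    otherwise,

a C1 cosine bump of compact support, so the healthy sections are exactly
cylindrical.  The computational grid is body-fitted: axial stations carry
radial lines scaled to the local wall radius via the normalized coordinate
eta = r / r_wall(z) in [0, 1], with optional geometric near-wall clustering.

All metric quantities (cell volumes, face areas and normals) are those of
the revolved quadrilaterals, computed exactly via Pappus' theorem, so
per-station annular areas partition the disc to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StenosedVesselSpec", "AxisymGrid", "wall_radius", "build_grid"]


@dataclass(frozen=True)
class StenosedVesselSpec:
    """Axisymmetric vessel with a cosine area-reduction bump.

    Lengths in metres.  severity is the area-reduction fraction in [0, 1);
    the default stenosis length (4 mm) sits inside the 2-6 mm range typical
    of the focal lesions this geometry idealizes.
    """

    inlet_radius: float = 1.5e-3
    length: float = 30e-3
    stenosis_center: float = 15e-3
    stenosis_length: float = 4e-3
    severity: float = 0.0

    def __post_init__(self) -> None:
        if self.inlet_radius <= 0.0 or self.length <= 0.0:
            raise ValueError("inlet_radius and length must be positive")
        if not (0.0 <= self.severity < 1.0):
            raise ValueError(f"severity must be in [0, 1), got {self.severity}")
        if not (0.0 < self.stenosis_length <= self.length):
            raise ValueError("stenosis_length must be in (0, length]")
        if not (0.0 <= self.stenosis_center <= self.length):
            raise ValueError("stenosis_center must lie inside the vessel")

    @property
    def throat_radius(self) -> float:
        return self.inlet_radius * np.sqrt(1.0 - self.severity)


def _bump(spec: StenosedVesselSpec, z: np.ndarray) -> np.ndarray:
    x = z - spec.stenosis_center
    inside = np.abs(x) <= spec.stenosis_length / 2.0
    b = np.zeros_like(np.asarray(z, dtype=float))
    b[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * x[inside] / spec.stenosis_length))
    return b


def _dbump_dz(spec: StenosedVesselSpec, z: np.ndarray) -> np.ndarray:
    x = z - spec.stenosis_center
    inside = np.abs(x) <= spec.stenosis_length / 2.0
    db = np.zeros_like(np.asarray(z, dtype=float))
    db[inside] = -(np.pi / spec.stenosis_length) * np.sin(
        2.0 * np.pi * x[inside] / spec.stenosis_length
    )
    return db


def wall_radius(spec: StenosedVesselSpec, z) -> np.ndarray | float:
    """Wall radius r(z), m; C1-smooth, exactly R0 outside the bump support.

    Raises
    ------
    ValueError
        If any z lies outside [0, length].
    """
    za = np.atleast_1d(np.asarray(z, dtype=float))
    if np.any((za < -1e-12) | (za > spec.length + 1e-12)):
        raise ValueError("z outside the vessel [0, length]")
    r = spec.inlet_radius * np.sqrt(1.0 - spec.severity * _bump(spec, za))
    return float(r[0]) if np.ndim(z) == 0 else r


def wall_slope(spec: StenosedVesselSpec, z) -> np.ndarray | float:
    """dr_wall/dz, analytic derivative of :func:`wall_radius`."""
    za = np.atleast_1d(np.asarray(z, dtype=float))
    b = _bump(spec, za)
    db = _dbump_dz(spec, za)
    s = spec.inlet_radius * (-spec.severity * db) / (
        2.0 * np.sqrt(1.0 - spec.severity * b)
    )
    return float(s[0]) if np.ndim(z) == 0 else s


def _radial_faces(n_radial: int, growth_rate: float) -> np.ndarray:
    """Normalized eta faces in [0, 1]; widths shrink geometrically toward the
    wall by ``growth_rate`` (1.0 = uniform)."""
    if growth_rate == 1.0:
        return np.linspace(0.0, 1.0, n_radial + 1)
    # width of cell j (axis j=0 ... wall j=n-1) proportional to g**(n-1-j)
    w = growth_rate ** np.arange(n_radial - 1, -1, -1, dtype=float)
    w /= w.sum()
    faces = np.concatenate(([0.0], np.cumsum(w)))
    faces[-1] = 1.0
    return faces


@dataclass
class AxisymGrid:
    """Structured body-fitted grid for the axisymmetric vessel.

    Cells are indexed (i, j): i axial (0..n_axial-1), j radial from axis
    (0..n_radial-1).  All areas/volumes are those of the revolved faces.
    """

    spec: StenosedVesselSpec
    z_faces: np.ndarray          # (Nz+1,)
    eta_faces: np.ndarray        # (Nr+1,)
    R_faces: np.ndarray          # (Nz+1,) wall radius at z faces
    z_centers: np.ndarray = field(init=False)
    R_centers: np.ndarray = field(init=False)
    dRdz_centers: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z_faces = np.asarray(self.z_faces, dtype=float)
        self.eta_faces = np.asarray(self.eta_faces, dtype=float)
        if np.any(np.diff(self.z_faces) <= 0.0):
            raise ValueError("axial coordinates must be strictly increasing")
        if np.any(self.R_faces <= 0.0):
            raise ValueError("wall radius must be positive everywhere")
        self.z_centers = 0.5 * (self.z_faces[:-1] + self.z_faces[1:])
        self.R_centers = np.asarray(wall_radius(self.spec, self.z_centers))
        self.dRdz_centers = np.asarray(wall_slope(self.spec, self.z_centers))
        self._build_metrics()

    # ---- metric construction -------------------------------------------
    def _build_metrics(self) -> None:
        zf, ef, Rf = self.z_faces, self.eta_faces, self.R_faces
        nz, nr = self.n_axial, self.n_radial
        # corner radii (Nz+1, Nr+1)
        self.r_corners = ef[None, :] * Rf[:, None]

        # cell polygon centroids and volumes (Pappus: V = 2*pi*rbar*A_poly)
        r_sw = self.r_corners[:-1, :-1]
        r_se = self.r_corners[1:, :-1]
        r_ne = self.r_corners[1:, 1:]
        r_nw = self.r_corners[:-1, 1:]
        z_w = zf[:-1][:, None]
        z_e = zf[1:][:, None]
        # shoelace over corners (counterclockwise in (z, r) plane)
        zs = np.stack([z_w + 0 * r_sw, z_e + 0 * r_se, z_e + 0 * r_ne, z_w + 0 * r_nw])
        rs = np.stack([r_sw, r_se, r_ne, r_nw])
        zs_n = np.roll(zs, -1, axis=0)
        rs_n = np.roll(rs, -1, axis=0)
        cross = zs * rs_n - zs_n * rs
        area2 = np.sum(cross, axis=0)                       # 2 * polygon area
        self.poly_area = 0.5 * area2
        if np.any(self.poly_area <= 0.0):
            raise ValueError("degenerate cell (non-positive polygon area)")
        self.zc = np.sum((zs + zs_n) * cross, axis=0) / (3.0 * area2)
        self.rc = np.sum((rs + rs_n) * cross, axis=0) / (3.0 * area2)
        self.volumes = 2.0 * np.pi * self.rc * self.poly_area
        if np.any(self.volumes <= 0.0):
            raise ValueError("non-positive cell volume")

        # axial faces (constant z): (Nz+1, Nr), annuli, normal = +z
        r_lo = self.r_corners[:, :-1]
        r_hi = self.r_corners[:, 1:]
        self.A_z = np.pi * (r_hi**2 - r_lo**2)
        self.rf_z = 0.5 * (r_lo + r_hi)                     # face midpoints

        # eta faces (constant eta): (Nz, Nr+1), revolved slanted segments
        dz_seg = (zf[1:] - zf[:-1])[:, None]
        dr_seg = self.r_corners[1:, :] - self.r_corners[:-1, :]
        s_len = np.sqrt(dz_seg**2 + dr_seg**2)
        r_mid = 0.5 * (self.r_corners[1:, :] + self.r_corners[:-1, :])
        self.A_eta = 2.0 * np.pi * r_mid * s_len
        # outward normal toward +eta: perpendicular to segment dir (dz, dr)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.n_eta_z = np.where(s_len > 0, -dr_seg / s_len, 0.0)
            self.n_eta_r = np.where(s_len > 0, dz_seg / s_len, 1.0)
        self.zf_eta = 0.5 * (zf[1:] + zf[:-1])[:, None] + 0.0 * r_mid
        self.rf_eta = r_mid

        # centroid-to-centroid distances across internal faces
        self.d_z = np.empty((nz + 1, nr))
        self.d_z[1:-1] = np.hypot(
            self.zc[1:] - self.zc[:-1], self.rc[1:] - self.rc[:-1]
        )
        self.d_z[0] = np.hypot(self.zc[0] - zf[0], self.rc[0] - self.rf_z[0])
        self.d_z[-1] = np.hypot(self.zc[-1] - zf[-1], self.rc[-1] - self.rf_z[-1])

        self.d_eta = np.empty((nz, nr + 1))
        self.d_eta[:, 1:-1] = np.hypot(
            self.zc[:, 1:] - self.zc[:, :-1], self.rc[:, 1:] - self.rc[:, :-1]
        )
        self.d_eta[:, 0] = np.hypot(
            self.zc[:, 0] - self.zf_eta[:, 0], self.rc[:, 0] - self.rf_eta[:, 0]
        )
        self.d_eta[:, -1] = np.hypot(
            self.zc[:, -1] - self.zf_eta[:, -1], self.rc[:, -1] - self.rf_eta[:, -1]
        )

        # wall geometry at cell columns
        slope = self.dRdz_centers
        norm = np.sqrt(1.0 + slope**2)
        self.wall_tangent = np.stack([1.0 / norm, slope / norm], axis=1)  # (z, r)
        self.wall_cos = 1.0 / norm
        # arc length along the wall at column centers
        seg = np.hypot(np.diff(self.z_faces), np.diff(self.R_faces))
        s_f = np.concatenate(([0.0], np.cumsum(seg)))
        self.wall_arclength = 0.5 * (s_f[:-1] + s_f[1:])
        # normal distances of the two near-wall cell rows to the wall,
        # evaluated in the mapped coordinate (positive by construction)
        eta_c = 0.5 * (ef[:-1] + ef[1:])
        self.wall_d1 = (1.0 - eta_c[-1]) * self.R_centers * self.wall_cos
        self.wall_d2 = (1.0 - eta_c[-2]) * self.R_centers * self.wall_cos

    # ---- basic properties ----------------------------------------------
    @property
    def n_axial(self) -> int:
        return self.z_faces.size - 1

    @property
    def n_radial(self) -> int:
        return self.eta_faces.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_axial, self.n_radial)

    @property
    def inlet_area(self) -> float:
        return float(np.pi * self.R_faces[0] ** 2)

    def nearest_column(self, z: float) -> int:
        """Index of the axial cell column whose center is nearest z."""
        return int(np.argmin(np.abs(self.z_centers - z)))


def build_grid(
    spec: StenosedVesselSpec,
    n_axial: int = 96,
    n_radial: int = 24,
    growth_rate: float = 1.2,
) -> AxisymGrid:
    """Structured body-fitted grid for the vessel.

    Parameters
    ----------
    n_axial, n_radial : int
        Cell counts (at least 16 x 8).
    growth_rate : float
        Geometric near-wall clustering factor for the radial spacing
        (1.0 = uniform; 1.2 shrinks cells toward the wall by that ratio).

    Raises
    ------
    ValueError
        If the resolution is below the 16 x 8 minimum.
    """
    if n_axial < 16 or n_radial < 8:
        raise ValueError(
            f"resolution below minimum 16x8: got {n_axial}x{n_radial}"
        )
    if growth_rate < 1.0:
        raise ValueError("growth_rate must be >= 1.0")
    z_faces = np.linspace(0.0, spec.length, n_axial + 1)
    eta_faces = _radial_faces(n_radial, growth_rate)
    R_faces = np.asarray(wall_radius(spec, z_faces))
    return AxisymGrid(spec=spec, z_faces=z_faces, eta_faces=eta_faces, R_faces=R_faces)
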