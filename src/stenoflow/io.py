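"""Tabular and legacy-VTK output helpers.

Probe series and wall-index tables go to CSV with explicit unit-bearing
column names.  Full fields are dumped as ASCII legacy-VTK structured grids
(cell-centered data), a deliberately simple text format that any VTK-aware
viewer reads directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import AxisymGrid

__all__ = ["probes_frame", "write_probes_csv", "write_vtk_structured"]

_FLOAT_FMT = "%.17g"


def probes_frame(solution) -> pd.DataFrame:
    """Long-format probe table: probe, z_m, time_s, velocity_m_per_s, pressure_Pa."""
    rows = []
    for name, data in solution.probes.items():
        for t, vel, ctr, pre in zip(solution.times, data["velocity"],
                                    data["centerline_velocity"], data["pressure"]):
            rows.append((name, data["z"], t, vel, ctr, pre))
    return pd.DataFrame(
        rows,
        columns=["probe", "z_m", "time_s", "velocity_m_per_s",
                 "centerline_velocity_m_per_s", "pressure_Pa"],
    )


def write_probes_csv(solution, path) -> None:
    probes_frame(solution).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_vtk_structured(path, grid: AxisymGrid, cell_data: dict[str, np.ndarray]) -> None:
    """ASCII legacy-VTK structured grid of the meridional (z, r) plane.

    Points are the grid corners; each entry of ``cell_data`` is an
    (n_axial, n_radial) array written as CELL_DATA.
    """
    nz1 = grid.z_faces.size
    nr1 = grid.eta_faces.size
    n_cells = (nz1 - 1) * (nr1 - 1)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("stenoflow axisymmetric meridional plane\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nz1} {nr1} 1\n")
        fh.write(f"POINTS {nz1 * nr1} double\n")
        for j in range(nr1):
            for i in range(nz1):
                fh.write(f"{grid.z_faces[i]:.9e} {grid.r_corners[i, j]:.9e} 0.0\n")
        fh.write(f"CELL_DATA {n_cells}\n")
        for name, arr in cell_data.items():
            a = np.asarray(arr)
            if a.shape != (nz1 - 1, nr1 - 1):
                raise ValueError(
                    f"cell data {name!r} has shape {a.shape}, expected "
                    f"{(nz1 - 1, nr1 - 1)}"
                )
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for j in range(nr1 - 1):
                for i in range(nz1 - 1):
                    fh.write(f"{a[i, j]:.9e}\n")
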