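"""Surface generation from pattern trajectories and mesh export.

The accreted pattern is the deformation history of a curve: stacking the
profile rows along the growth-time coordinate produces a surface.  Three
geometries are supported:

* ``strip`` — rows stacked along a straight growth axis (the widening strip
  swept by the generative zone; width follows ``L(t)``);
* ``disc`` — the arc coordinate is mapped to an angle on a circle whose
  radius grows with ``L(t)``, so the pattern history reads radially outward
  (mushroom-gill / coral motif);
* ``helicospiral`` — the profile is applied as a normal displacement to a
  logarithmically coiling generating curve, dressing a smooth shell with the
  computed ridge pattern.

Meshes are triangulated vertex grids exported through :mod:`trimesh` as OBJ
or PLY.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pattern import PatternTrajectory

__all__ = ["PatternSurface", "sweep_surface", "export_mesh"]

GEOMETRIES = ("strip", "disc", "helicospiral")


@dataclass
class PatternSurface:
    """Triangulated surface recording a pattern trajectory."""

    vertices: np.ndarray  # (n_t * n_x, 3)
    faces: np.ndarray  # (n_faces, 3) int
    geometry: str
    shape: tuple[int, int]  # (n_t, n_x)

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _grid_faces(nt: int, nx: int) -> np.ndarray:
    """Two triangles per quad of an (nt, nx) vertex grid."""
    i, j = np.meshgrid(np.arange(nt - 1), np.arange(nx - 1), indexing="ij")
    v00 = (i * nx + j).ravel()
    v01 = v00 + 1
    v10 = v00 + nx
    v11 = v10 + 1
    upper = np.stack([v00, v10, v01], axis=1)
    lower = np.stack([v01, v10, v11], axis=1)
    return np.concatenate([upper, lower], axis=0)


def _profiles(traj: PatternTrajectory, n_x: int, stride: int):
    """Material-coordinate profiles y(xi, t_i) for the stored times."""
    idx = np.arange(0, len(traj.t), stride)
    xi = np.linspace(-1.0, 1.0, n_x)
    rows = []
    for i in idx:
        ti = traj.t[i]
        L = float(traj.schedule.L(ti))
        active = traj.active_levels(i)
        if active and any(traj.amplitudes[lv.level][i] > 0 for lv in active):
            pat = traj.pattern_at(i)
            y = pat.profile(xi * L)
        else:
            y = np.zeros_like(xi)
        rows.append((ti, L, y))
    return xi, rows


def sweep_surface(
    traj: PatternTrajectory,
    geometry: str = "strip",
    n_x: int = 257,
    stride: int = 10,
    pitch: float = 1.0,
    disc_r0: float = 0.5,
    helico_r0: float = 0.3,
    helico_coil: float = 0.12,
    helico_turns: float = 3.0,
    helico_drop: float = 0.35,
) -> PatternSurface:
    """Sweep a trajectory into a surface in the requested geometry.

    ``stride`` subsamples the stored times (one profile row per kept time).
    For the helicospiral the generating curve is ``r = r0 exp(coil * phi)``
    with ``phi`` winding ``helico_turns`` turns over the trajectory and the
    apex dropping at rate ``helico_drop``.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"unknown geometry {geometry!r}; expected one of {GEOMETRIES}")
    if traj.t.size == 0:
        raise ValueError("trajectory is empty")
    xi, rows = _profiles(traj, n_x, stride)
    nt = len(rows)
    verts = np.zeros((nt, n_x, 3))
    if geometry == "strip":
        for r, (ti, L, y) in enumerate(rows):
            verts[r, :, 0] = xi * L
            verts[r, :, 1] = ti * pitch
            verts[r, :, 2] = y
    elif geometry == "disc":
        span = 2.0 * math.pi * 0.92  # leave a seam so the mesh stays manifold
        for r, (ti, L, y) in enumerate(rows):
            rad = disc_r0 + ti * pitch
            theta = xi * span / 2.0
            verts[r, :, 0] = rad * np.cos(theta)
            verts[r, :, 1] = rad * np.sin(theta)
            verts[r, :, 2] = y
    else:  # helicospiral
        t_lo, t_hi = rows[0][0], rows[-1][0]
        span_t = max(t_hi - t_lo, 1e-12)
        for r, (ti, L, y) in enumerate(rows):
            frac = (ti - t_lo) / span_t
            phi = 2.0 * math.pi * helico_turns * frac
            rad = helico_r0 * math.exp(helico_coil * phi)
            centre = np.array(
                [rad * math.cos(phi), rad * math.sin(phi), -helico_drop * rad]
            )
            # cross-section along the radial direction, ridges displace along z
            # with relief scaled to the local whorl radius
            d_rad = np.array([math.cos(phi), math.sin(phi), 0.0])
            half_w = L * rad / max(rows[0][1], 1e-12) * 0.25
            pts = centre[None, :] + np.outer(xi * half_w, d_rad)
            pts[:, 2] += y * 0.1 * rad
            verts[r] = pts
    faces = _grid_faces(nt, n_x)
    return PatternSurface(
        vertices=verts.reshape(-1, 3), faces=faces, geometry=geometry, shape=(nt, n_x)
    )


def export_mesh(surface: PatternSurface, path: str, fmt: str | None = None) -> str:
    """Write the surface as OBJ or PLY (ASCII); returns the path written.

    The format is inferred from the filename suffix unless given explicitly.
    The written mesh round-trips through any standard mesh reader.
    """
    import trimesh

    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}; use 'obj' or 'ply'")
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    kwargs = {"encoding": "ascii"} if fmt == "ply" else {}
    data = trimesh.exchange.export.export_mesh(mesh, path, file_type=fmt, **kwargs)
    return str(path)
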