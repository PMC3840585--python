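"""Geometric visualization products, computed as data.

Two families:

* Sanson-Flamsteed (sinusoidal) projections of principal-axis directions,
  optionally carrying the order-parameter magnitude as a height so a "top
  view" reproduces the classic 2D plot while a side view separates tensors
  that share an orientation but differ in alignment magnitude.
* Acceptable-orientation bands on the unit sphere for a single coupling: the
  set of directions v with |(dmax/r^3) v.S.v - D_target| <= tol.  These are
  the bands a molecular viewer would draw around a bond vector; here they
  are returned as boolean spherical masks plus an area fraction.

Rendering is deliberately out of scope; every product is a plain table or
grid that any plotting tool can consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SaupeTensor
from .tensor import diagonalize

__all__ = ["SFPoint", "OrientationBand", "sf_project", "sf_plot_data",
           "orientation_band", "sf_points_to_tsv"]


@dataclass(frozen=True)
class SFPoint:
    axis_label: str  # "x", "y" or "z" principal axis
    lon: float  # rad, (-pi, pi]
    lat: float  # rad, [-pi/2, pi/2]
    px: float  # lon * cos(lat)
    py: float  # lat
    height: float  # |order parameter| for that axis; 0.0 in 2d mode


def sf_project(direction) -> tuple[float, float, float, float]:
    """Sinusoidal (equal-area) projection of a unit direction.

    Returns ``(lon, lat, px, py)`` with ``lat = arcsin(z)``,
    ``lon = atan2(y, x)``, ``px = lon*cos(lat)``, ``py = lat``.
    """
    x, y, z = np.asarray(direction, dtype=float)
    lat = float(np.arcsin(np.clip(z, -1.0, 1.0)))
    lon = float(np.arctan2(y, x))
    return lon, lat, lon * np.cos(lat), lat


def _tensor_points(tensor: SaupeTensor, mode: str) -> list[SFPoint]:
    decomp = diagonalize(tensor)
    points = []
    for k, label in enumerate(("x", "y", "z")):
        height = abs(decomp.principal[k]) if mode == "3d" else 0.0
        axis = decomp.rotation[:, k]
        for direction in (axis, -axis):
            lon, lat, px, py = sf_project(direction)
            points.append(SFPoint(label, lon, lat, px, py, height))
    return points


def sf_plot_data(ensemble, mode: str = "2d") -> list[SFPoint]:
    """Project the principal axes of every tensor in a solution ensemble.

    Both antipodes of each axis are emitted (the physics cannot tell them
    apart).  ``ensemble`` is a :class:`~rdcfit.analysis.SolutionEnsemble`;
    the best-fit tensor comes first, then each accepted Monte Carlo tensor.
    """
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    points = []
    for tensor in [ensemble.best.tensor, *ensemble.accepted]:
        points.extend(_tensor_points(tensor, mode))
    return points


def sf_points_to_tsv(points) -> str:
    """Tab-separated table (axis, lon, lat, px, py, height) for plotting tools."""
    lines = ["axis\tlon\tlat\tpx\tpy\theight"]
    for p in points:
        lines.append(
            f"{p.axis_label}\t{p.lon:.10g}\t{p.lat:.10g}\t{p.px:.10g}\t{p.py:.10g}\t{p.height:.10g}"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class OrientationBand:
    grid: np.ndarray  # boolean, shape (n_lat, n_lon), cell-center evaluation
    lats: np.ndarray  # cell-center latitudes, rad
    lons: np.ndarray  # cell-center longitudes, rad
    accepted_fraction: float  # cos(lat)-weighted area fraction in [0, 1]
    tolerance: float  # Hz
    target: float  # Hz


def orientation_band(
    tensor: SaupeTensor,
    dmax_over_r3: float,
    d_target: float,
    tol: float,
    resolution: int = 256,
) -> OrientationBand:
    """Directions on the sphere whose back-calculated coupling lies within
    ``tol`` (Hz) of ``d_target``.

    The sphere is sampled on an equiangular lat x lon grid (``resolution``
    latitude rows, ``2*resolution`` longitude columns) at cell centers; the
    accepted fraction is the cos(lat)-weighted mean of the mask, a midpoint
    quadrature of the band's solid-angle fraction.
    """
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if resolution < 8:
        raise ValueError("resolution must be >= 8")
    n_lat, n_lon = resolution, 2 * resolution
    # Build the grid with exact antipodal symmetry: the antipode of cell
    # (i, j) is (n_lat-1-i, (j + n_lon/2) mod n_lon), and the coordinate
    # arrays are constructed so that its direction is the exact floating-
    # point negation.  Trig identities alone would only be symmetric to
    # rounding error.
    half = (np.arange(n_lat // 2) + 0.5) / n_lat * np.pi - np.pi / 2  # < 0
    mid = [0.0] if n_lat % 2 else []
    lats = np.concatenate([half, mid, -half[::-1]])
    cos_lat = np.concatenate([np.cos(half), [1.0] if mid else [], np.cos(half)[::-1]])
    sin_lat = np.concatenate([np.sin(half), mid, -np.sin(half)[::-1]])
    lon_half = (np.arange(n_lon // 2) + 0.5) / n_lon * 2 * np.pi - np.pi  # < 0
    lons = np.concatenate([lon_half, lon_half + np.pi])
    cos_lon = np.concatenate([np.cos(lon_half), -np.cos(lon_half)])
    sin_lon = np.concatenate([np.sin(lon_half), -np.sin(lon_half)])
    x = cos_lat[:, None] * cos_lon[None, :]
    y = cos_lat[:, None] * sin_lon[None, :]
    z = sin_lat[:, None] * np.ones(n_lon)[None, :]
    m = tensor.matrix
    quad = (
        m[0, 0] * x * x + m[1, 1] * y * y + m[2, 2] * z * z
        + 2 * (m[0, 1] * x * y + m[0, 2] * x * z + m[1, 2] * y * z)
    )
    grid = np.abs(dmax_over_r3 * quad - d_target) <= tol
    weights = np.repeat(cos_lat[:, None], n_lon, axis=1)
    accepted = float((grid * weights).sum() / weights.sum())
    return OrientationBand(
        grid=grid, lats=lats, lons=lons,
        accepted_fraction=accepted, tolerance=tol, target=d_target,
    )
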