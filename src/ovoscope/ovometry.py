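"""Egg morphometry from the region-of-interest outline.

The egg outline (a closed polygon drawn on the photograph) is treated as
the silhouette of a solid of revolution: the long axis is the direction
through the two most distant boundary points, the radius function r(t) is
the mean of the two perpendicular half-widths at stations along that axis,
and volume / surface follow from the classical formulas

    V = pi * int r(t)^2 dt
    S = 2*pi * int r(t) * sqrt(1 + r'(t)^2) dt

integrated by the composite trapezoid rule, with r' from central
differences (one-sided at the poles).  The surface-to-volume ratio sv = S/V
(1/mm) is the egg-size covariate of the statistical stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "EggProfile",
    "EggMetrics",
    "GeometryError",
    "calibrate_scale",
    "extract_profile",
    "volume_surface",
]


class GeometryError(ValueError):
    pass


@dataclass
class EggProfile:
    """Radius-vs-station description of the revolved egg outline.

    ``axis_unit`` and ``endpoints`` are in pixel coordinates; ``stations``
    (positions along the axis) and ``radii`` are in mm.
    """

    axis_unit: np.ndarray
    endpoints: np.ndarray  # (2, 2) px, the two poles
    stations: np.ndarray  # (N+1,) mm, strictly increasing, 0 at first pole
    radii: np.ndarray  # (N+1,) mm, 0 at both poles
    mm_per_px: float

    def __post_init__(self) -> None:
        self.stations = np.asarray(self.stations, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(self.stations) <= 0):
            raise GeometryError("stations must be strictly increasing")
        if np.any(self.radii < 0):
            raise GeometryError("radii must be non-negative")


@dataclass
class EggMetrics:
    volume_mm3: float
    surface_mm2: float

    @property
    def sv_per_mm(self) -> float:
        return self.surface_mm2 / self.volume_mm3


def calibrate_scale(scale_points: np.ndarray, known_mm: float) -> float:
    """mm per pixel from the two endpoints of the photographed scale bar."""
    pts = np.asarray(scale_points, dtype=float)
    if pts.shape != (2, 2):
        raise ValueError("scale_points must be two (x, y) coordinates")
    if known_mm <= 0:
        raise ValueError("known_mm must be positive")
    d = float(np.hypot(*(pts[1] - pts[0])))
    if d == 0:
        raise GeometryError("scale bar endpoints coincide")
    return known_mm / d


def extract_profile(
    roi: np.ndarray, mm_per_px: float, n_stations: int = 200
) -> EggProfile:
    """Long axis and symmetrized radius function of the outline polygon.

    The long axis runs through the two most distant boundary vertices.  At
    each of ``n_stations`` interior stations the outline is cut
    perpendicular to the axis and the radius is the mean of the two
    half-widths (the revolved solid cannot represent bilateral asymmetry,
    so the outline is symmetrized).
    """
    poly = np.asarray(roi, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise GeometryError("RoI must be an (N>=3, 2) polygon")
    shape = Polygon(poly)
    if not shape.is_valid:
        raise GeometryError("RoI polygon is self-intersecting or degenerate")
    if n_stations < 50:
        raise ValueError("need at least 50 stations")

    # most distant vertex pair (outlines here have a few hundred vertices)
    d2 = ((poly[:, None, :] - poly[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    p0, p1 = poly[i], poly[j]
    axis = p1 - p0
    length_px = float(np.hypot(*axis))
    u = axis / length_px
    v = np.array([-u[1], u[0]])  # perpendicular

    # half-width extent for cutting chords
    proj_perp = (poly - p0) @ v
    halfspan = float(np.abs(proj_perp).max()) * 1.5 + 2.0

    t_px = np.linspace(0.0, length_px, n_stations + 1)
    radii_px = np.zeros_like(t_px)
    for k in range(1, n_stations):
        c = p0 + t_px[k] * u
        chord = LineString([c - halfspan * v, c + halfspan * v])
        cut = chord.intersection(shape)
        if cut.is_empty:
            continue
        coords = []
        geoms = getattr(cut, "geoms", [cut])
        for g in geoms:
            coords.extend(np.asarray(g.coords))
        offs = (np.asarray(coords) - c) @ v
        # mean of the two perpendicular half-widths
        radii_px[k] = 0.5 * (offs.max() - offs.min())

    return EggProfile(
        axis_unit=u,
        endpoints=np.array([p0, p1]),
        stations=t_px * mm_per_px,
        radii=radii_px * mm_per_px,
        mm_per_px=float(mm_per_px),
    )


def volume_surface(profile: EggProfile) -> EggMetrics:
    """Volume and surface of the revolved profile (trapezoid quadrature)."""
    t, r = profile.stations, profile.radii
    if np.any(r < 0):
        raise GeometryError("negative radius in profile")
    volume = np.pi * np.trapezoid(r**2, t)
    drdt = np.gradient(r, t)  # central differences, one-sided at poles
    surface = 2 * np.pi * np.trapezoid(r * np.sqrt(1 + drdt**2), t)
    if volume <= 0 or surface <= 0:
        raise GeometryError("degenerate profile")
    return EggMetrics(volume_mm3=float(volume), surface_mm2=float(surface))
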