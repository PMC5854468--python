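"""Geometry of closed cell contours.

Everything downstream of segmentation works on a closed polyline traced
around a single cell in the image plane: per-vertex sidewall curvature
(the in-plane principal curvature ``kappa1``), a midline-plus-ribs "pill
mesh" giving local widths, the ratio of the two principal curvatures
(``kappa2`` is inferred from the cell width assuming radial symmetry),
the tangent-angle correlation function G(l) of the contour, and
doubling times from exponential fits of projected cell area.

Units: vertices are in micrometres; curvature in 1/um; angles in degrees.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CellContour",
    "WidthProfile",
    "CurvatureProfile",
    "GrowthFit",
    "sidewall_curvature",
    "pill_mesh",
    "principal_curvature_ratio",
    "track_local_curvature",
    "tangential_correlation",
    "doubling_time",
]

#: aspect ratio of the principal axes below which a cell is treated as
#: round (no measurable long axis, hence no midline).
ROUND_ASPECT_THRESHOLD = 1.1


@dataclass(frozen=True)
class CellContour:
    """A closed, simple polyline around one cell.

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of (x, y) positions in um.  A duplicated closing
        vertex is dropped; closure is implicit.  The polyline is
        re-oriented counter-clockwise at construction so that convex
        (outward-bulging) regions have positive signed curvature.
    pixel_size
        Camera pixel size in um; sets the arc-length window of the
        two-pixel curvature smoothing.
    """

    vertices: np.ndarray
    pixel_size: float = 0.065

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError("a contour needs at least 3 distinct vertices")
        edges = np.diff(np.vstack([v, v[:1]]), axis=0)
        if np.any(np.hypot(edges[:, 0], edges[:, 1]) == 0.0):
            raise ValueError("degenerate contour: repeated consecutive vertices")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        # enforce CCW orientation (positive signed area)
        area2 = np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1])
        if area2 < 0:
            v = v[::-1]
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def principal_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Centroid, unit long axis, and sqrt-eigenvalue extents of the vertex cloud."""
        c = self.vertices.mean(axis=0)
        cov = np.cov((self.vertices - c).T)
        w, vec = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        return c, vec[:, order[0]], np.sqrt(np.maximum(w[order], 0.0))

    @property
    def aspect_ratio(self) -> float:
        _, _, ext = self.principal_axes()
        return float(ext[0] / ext[1]) if ext[1] > 0 else math.inf

    @property
    def is_round(self) -> bool:
        return self.aspect_ratio <= ROUND_ASPECT_THRESHOLD


@dataclass(frozen=True)
class WidthProfile:
    """Pill-mesh output: midline stations, per-station widths, cell width."""

    midline: np.ndarray | None
    midline_angles_deg: np.ndarray | None
    segment_widths: np.ndarray
    cell_width: float
    is_round: bool

    def local_width(self, point: np.ndarray, k: int = 10) -> float:
        """Mean of the ``k`` station widths nearest to ``point`` (um).

        Follows the convention of averaging the widths of the nearest
        mesh points around a trajectory.
        """
        if self.midline is None:
            return self.cell_width
        d = np.hypot(*(self.midline - np.asarray(point, float)).T)
        idx = np.argsort(d, kind="stable")[: min(k, len(d))]
        return float(np.mean(self.segment_widths[idx]))

    def nearest_station(self, point: np.ndarray) -> int:
        """Index of the midline station closest to ``point`` (ties -> lower index)."""
        if self.midline is None:
            raise ValueError("round cell: no midline")
        d = np.hypot(*(self.midline - np.asarray(point, float)).T)
        return int(np.argmin(d))


@dataclass(frozen=True)
class CurvatureProfile:
    """Signed sidewall curvature and the principal-curvature ratio."""

    kappa1: np.ndarray          # per-vertex, 1/um, positive = convex outward
    kappa2: float               # 1/r_cell, 1/um
    ratio: float                # mean flank kappa1 / kappa2
    flank_mask: np.ndarray      # vertices contributing to the flank mean


def _triplet_curvature(v: np.ndarray) -> np.ndarray:
    """Signed curvature of the circle through each vertex triple (wrapping).

    kappa = 2 * cross(a, b) / (|a| |b| |c|) with a, b the incoming and
    outgoing edges and c the spanning chord; positive for left turns,
    i.e. convex vertices of a CCW contour.  Collinear triples give 0.
    """
    prev_ = np.roll(v, 1, axis=0)
    next_ = np.roll(v, -1, axis=0)
    a = v - prev_
    b = next_ - v
    c = next_ - prev_
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    denom = np.hypot(*a.T) * np.hypot(*b.T) * np.hypot(*c.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
    return kappa


def sidewall_curvature(contour: CellContour) -> np.ndarray:
    """Per-vertex signed sidewall curvature (1/um).

    Computed from three successive contour points (the circumscribed
    circle of each vertex triple) and boxcar-smoothed over a window of
    two pixels' worth of arc length.  The contour is closed, so the
    window wraps around the endpoints.
    """
    v = contour.vertices
    kappa = _triplet_curvature(v)
    mean_edge = contour.perimeter / contour.n_vertices
    window = max(1, round(2.0 * contour.pixel_size / mean_edge))
    if window % 2 == 0:
        window += 1
    if window > 1:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.concatenate([kappa[-pad:], kappa, kappa[:pad]])
        kappa = np.convolve(padded, kernel, mode="valid")
    return kappa


def _max_inscribed_diameter(poly: Polygon) -> float:
    try:
        radius_line = shapely.maximum_inscribed_circle(poly, tolerance=1e-6)
        return 2.0 * radius_line.length
    except AttributeError:  # older GEOS: fall back to centroid clearance
        return 2.0 * poly.exterior.distance(poly.centroid)


def pill_mesh(contour: CellContour, n_stations: int = 64) -> WidthProfile:
    """Midline and perpendicular-segment widths of an elongated contour.

    Stations are spaced along the principal (long) axis; at each station
    the chord perpendicular to the axis is clipped to the contour, its
    length recorded as the local width and its midpoint as a midline
    point.  The cell width is the maximum width along the length of the
    cell.  Contours whose principal-axis aspect ratio is below
    ``ROUND_ASPECT_THRESHOLD`` have no long axis: they are flagged round,
    the midline is absent, and the width is the maximum inscribed
    diameter.
    """
    poly = contour.polygon()
    if contour.is_round:
        w = _max_inscribed_diameter(poly)
        return WidthProfile(None, None, np.array([w]), float(w), True)

    center, axis, ext = contour.principal_axes()
    normal = np.array([-axis[1], axis[0]])
    t = (contour.vertices - center) @ axis
    t_lo, t_hi = t.min(), t.max()
    span = t_hi - t_lo
    stations = np.linspace(t_lo + 0.01 * span, t_hi - 0.01 * span, n_stations)
    half = 1.5 * float(np.hypot(*(contour.vertices - center).T).max())

    mid_pts, widths = [], []
    for s in stations:
        base = center + s * axis
        chord = LineString([base - half * normal, base + half * normal])
        cut = poly.intersection(chord)
        if cut.is_empty:
            continue
        if cut.geom_type == "MultiLineString":
            cut = max(cut.geoms, key=lambda g: g.length)
        if cut.geom_type != "LineString" or cut.length == 0:
            continue
        widths.append(cut.length)
        mid_pts.append(np.asarray(cut.interpolate(0.5, normalized=True).coords[0]))

    if len(widths) < 2:
        w = _max_inscribed_diameter(poly)
        return WidthProfile(None, None, np.array([w]), float(w), True)

    midline = np.asarray(mid_pts)
    widths = np.asarray(widths)
    if len(midline) >= 3:  # light smoothing of the centerline
        sm = midline.copy()
        sm[1:-1] = (midline[:-2] + midline[1:-1] + midline[2:]) / 3.0
        midline = sm
    d = np.gradient(midline, axis=0)
    angles = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 180.0
    return WidthProfile(midline, angles, widths, float(widths.max()), False)


def principal_curvature_ratio(
    contour: CellContour,
    width_profile: WidthProfile | None = None,
    flank_fraction: float = 0.8,
) -> CurvatureProfile:
    """Ratio of in-plane (sidewall) to radial principal curvature.

    The radial curvature is ``kappa2 = 1 / r_cell`` with ``r_cell`` half
    the cell width, assuming the cell is radially symmetric about its
    midline.  The sidewall curvature entering the ratio is averaged over
    the flank: for elongated cells, vertices within the central
    ``flank_fraction`` of the long axis (polar caps excluded); for round
    cells, all vertices.  A ratio near 1 means the two principal
    curvatures are similar, i.e. the cell is round.

    The polar caps are excluded from the flank mean: at least
    ``(1 - flank_fraction) / 2`` of the long-axis extent at each end,
    widened to half the cell width when that is larger (the cap of a
    spherocylinder is exactly that deep).
    """
    if width_profile is None:
        width_profile = pill_mesh(contour)
    if width_profile.cell_width <= 0:
        raise ValueError("zero cell width: curvature ratio undefined")
    kappa1 = sidewall_curvature(contour)
    if width_profile.is_round:
        mask = np.ones(contour.n_vertices, dtype=bool)
    else:
        center, axis, _ = contour.principal_axes()
        t = (contour.vertices - center) @ axis
        length = t.max() - t.min()
        cut = max((1.0 - flank_fraction) / 2.0 * length, width_profile.cell_width / 2.0)
        mask = (t >= t.min() + cut) & (t <= t.max() - cut)
        if not mask.any():
            mask = np.ones(contour.n_vertices, dtype=bool)
    kappa2 = 1.0 / (width_profile.cell_width / 2.0)
    ratio = float(np.mean(kappa1[mask]) / kappa2)
    return CurvatureProfile(kappa1, kappa2, ratio, mask)


def track_local_curvature(contour: CellContour, point: np.ndarray, k: int = 3) -> float:
    """Mean sidewall curvature of the ``k`` nearest contour points on each side.

    The two "sides" are the halves of the contour on either side of the
    long axis; for a round cell the plain ``2k`` nearest vertices are
    used instead.
    """
    kappa1 = sidewall_curvature(contour)
    point = np.asarray(point, float)
    d = np.hypot(*(contour.vertices - point).T)
    if contour.is_round:
        idx = np.argsort(d, kind="stable")[: 2 * k]
        return float(np.mean(kappa1[idx]))
    center, axis, _ = contour.principal_axes()
    normal = np.array([-axis[1], axis[0]])
    side = (contour.vertices - center) @ normal >= 0
    picks = []
    for s in (side, ~side):
        ids = np.flatnonzero(s)
        if len(ids):
            picks.extend(ids[np.argsort(d[ids], kind="stable")[:k]])
    return float(np.mean(kappa1[picks]))


def tangential_correlation(contour: CellContour, max_arc: float) -> pd.DataFrame:
    """Tangent-angle correlation G(l) of a closed contour.

    Each edge gets a directed tangent angle ``theta_i = atan2(dy, dx)``;
    the correlation at vertex separation n is
    ``G(n) = mean_i cos(theta_{i+n} - theta_i)`` (indices wrap), and n is
    converted to arc length ``l`` using the mean edge length.  A straight
    polyline gives G = 1 at every l; a circle of radius r gives
    G(l) = cos(l / r).

    Returns a tidy table with columns ``l_um`` and ``G`` (the l = 0 row,
    G = 1, included).
    """
    v = contour.vertices
    if max_arc >= contour.perimeter / 2:
        raise ValueError("max_arc must be below half the perimeter")
    edges = np.roll(v, -1, axis=0) - v
    theta = np.arctan2(edges[:, 1], edges[:, 0])
    mean_edge = contour.perimeter / contour.n_vertices
    n_max = int(max_arc / mean_edge)
    ls, gs = [0.0], [1.0]
    for n in range(1, n_max + 1):
        gs.append(float(np.mean(np.cos(np.roll(theta, -n) - theta))))
        ls.append(n * mean_edge)
    return pd.DataFrame({"l_um": ls, "G": gs})


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth fit of projected cell area."""

    rate_per_min: float
    doubling_time_min: float
    growing: bool


def doubling_time(areas, times) -> GrowthFit:
    """Doubling time from the slope of log area vs time.

    Fits a line through (t, ln area); the doubling time is ln 2 / slope.
    Non-growing series (slope <= 0) are flagged and carry no doubling
    time.
    """
    areas = np.asarray(areas, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(areas) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    slope, _ = np.polyfit(times, np.log(areas), 1)
    if slope <= 1e-12:  # constant series fit to float noise is not growth
        return GrowthFit(float(slope), math.nan, False)
    return GrowthFit(float(slope), float(math.log(2.0) / slope), True)
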