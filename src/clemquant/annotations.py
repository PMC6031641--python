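"""Domain types and the planar geometry kernel.

Everything downstream (density estimation, stereology, resolution
measurement, pit mapping) works on :class:`MicrographAnnotation` objects:
a physical calibration (:class:`ImageFrame`), one or more segmented
membrane polylines (:class:`MembraneContour`) and a set of electron-dense
particle centers (:class:`Particle`).  All geometry is 2-D and in
nanometres; pixel coordinates are converted once, at read time.

Coordinate convention: 0-based pixel indices, x rightward, y downward
(raster order).  Sidedness of a directed polyline is defined by the sign
of the 2-D cross product ``(v2-v1) x (q-v1)``: positive is the "left"
side.  Which side is cytoplasmic is declared per contour via
``side_convention`` ("left" or "right").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ImageFrame",
    "MembraneContour",
    "Particle",
    "MicrographAnnotation",
    "arc_length",
    "point_at_arc",
    "closest_approach",
    "closest_approach_many",
    "SIDE_CYTOPLASM",
    "SIDE_EXTRACELLULAR",
    "SIDE_ON_MEMBRANE",
]

SIDE_CYTOPLASM = 1
SIDE_EXTRACELLULAR = -1
SIDE_ON_MEMBRANE = 0


@dataclass(frozen=True)
class ImageFrame:
    """Physical calibration of one micrograph.

    ``nm_per_px`` scales pixel coordinates to nanometres;
    ``section_thickness_nm`` (default 70, ultrathin serial sections) turns
    areas into volumes.
    """

    width_px: int
    height_px: int
    nm_per_px: float
    section_thickness_nm: float = 70.0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("frame dimensions must be >= 1 px")
        if self.nm_per_px <= 0:
            raise ValueError("nm_per_px must be positive")
        if self.section_thickness_nm <= 0:
            raise ValueError("section_thickness_nm must be positive")

    @property
    def width_nm(self) -> float:
        return self.width_px * self.nm_per_px

    @property
    def height_nm(self) -> float:
        return self.height_px * self.nm_per_px

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm


class MembraneContour:
    """A directed membrane polyline with optional coat and pit marks.

    Parameters
    ----------
    vertices:
        (N, 2) array of points in nm, N >= 2.
    coat_intervals:
        Arc-length ranges ``[s0, s1]`` (nm along the polyline) flagged as
        clathrin-coated.  Must be non-overlapping and inside
        ``[0, total_length]``.
    pit_marks:
        Optional ``(pit_start, pit_end)`` arc positions bracketing a
        coated-pit profile, ``pit_start < pit_end``.
    side_convention:
        "left" if the cytoplasm lies on the left of the directed
        polyline (positive cross product), "right" otherwise.
    """

    def __init__(
        self,
        vertices: Sequence[Sequence[float]] | np.ndarray,
        coat_intervals: Sequence[tuple[float, float]] = (),
        pit_marks: tuple[float, float] | None = None,
        side_convention: str = "left",
    ) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("vertices must be an (N, 2) array with N >= 2")
        if side_convention not in ("left", "right"):
            raise ValueError("side_convention must be 'left' or 'right'")
        self.vertices = v
        self.side_convention = side_convention

        seg = np.diff(v, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.all(seglen == 0):
            raise ValueError("degenerate contour: all vertices identical")
        self._seg = seg
        self._seglen = seglen
        self._cumlen = np.concatenate([[0.0], np.cumsum(seglen)])
        total = self._cumlen[-1]

        ivals = [(float(a), float(b)) for a, b in coat_intervals]
        for a, b in ivals:
            if not (0.0 <= a < b <= total + 1e-9):
                raise ValueError(
                    f"coat interval [{a}, {b}] outside [0, {total:.3f}]"
                )
        ivals.sort()
        for (_, b0), (a1, _) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError("coat intervals overlap")
        self.coat_intervals = ivals

        if pit_marks is not None:
            p0, p1 = float(pit_marks[0]), float(pit_marks[1])
            if not (0.0 <= p0 < p1 <= total + 1e-9):
                raise ValueError("pit marks must satisfy 0 <= start < end <= total")
            pit_marks = (p0, p1)
        self.pit_marks = pit_marks

    @property
    def total_length(self) -> float:
        return float(self._cumlen[-1])

    def in_coat(self, s: float | np.ndarray) -> np.ndarray:
        """True where arc position ``s`` falls inside a coat interval (closed)."""
        s = np.asarray(s, dtype=float)
        out = np.zeros(s.shape, dtype=bool)
        for a, b in self.coat_intervals:
            out |= (s >= a) & (s <= b)
        return out

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0)) -> "MembraneContour":
        """Rigidly transformed copy (used by invariance tests and mapping)."""
        th = np.radians(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        v = self.vertices @ R.T + np.asarray(translation, dtype=float)
        return MembraneContour(v, self.coat_intervals, self.pit_marks, self.side_convention)


@dataclass(frozen=True)
class Particle:
    """An electron-dense particle center, ~7 nm nominal diameter."""

    center: tuple[float, float]
    nominal_diameter_nm: float = 7.0

    def __post_init__(self) -> None:
        if self.nominal_diameter_nm <= 0:
            raise ValueError("nominal_diameter_nm must be positive")


@dataclass
class MicrographAnnotation:
    """One micrograph's segmentation: frame, contours, particles, labels."""

    frame: ImageFrame
    contours: list[MembraneContour]
    particles: list[Particle]
    condition: str = ""
    experiment_id: str = ""
    image_index: int = 0

    def __post_init__(self) -> None:
        w, h = self.frame.width_nm, self.frame.height_nm
        for p in self.particles:
            x, y = p.center
            if not (-1e-6 <= x <= w + 1e-6 and -1e-6 <= y <= h + 1e-6):
                raise ValueError(f"particle at ({x}, {y}) nm outside frame bounds")

    def particle_array(self) -> np.ndarray:
        if not self.particles:
            return np.empty((0, 2))
        return np.asarray([p.center for p in self.particles], dtype=float)


# ---------------------------------------------------------------------------
# geometry kernel


def arc_length(contour: MembraneContour, upto: int | float | None = None) -> float:
    """Arc length of a contour, total or up to a vertex index / arc position.

    ``upto=None`` gives the total length; an ``int`` is a vertex index
    (cumulative length at that vertex); a ``float`` is an arc position,
    validated against ``[0, total]`` and returned unchanged.
    """
    if upto is None:
        return contour.total_length
    if isinstance(upto, (int, np.integer)):
        n = contour.vertices.shape[0]
        if not (0 <= upto < n):
            raise IndexError(f"vertex index {upto} out of range [0, {n})")
        return float(contour._cumlen[upto])
    s = float(upto)
    if not (0.0 <= s <= contour.total_length + 1e-9):
        raise ValueError(f"arc position {s} outside [0, {contour.total_length:.3f}]")
    return min(s, contour.total_length)


def point_at_arc(contour: MembraneContour, s: float | np.ndarray):
    """Point, unit tangent, and cytoplasmic unit normal at arc position(s).

    Arc positions inside a zero-length run of duplicate vertices resolve to
    that vertex with the tangent of the next nonzero segment.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s < -1e-9) or np.any(s > contour.total_length + 1e-9):
        raise ValueError("arc position outside contour")
    s = np.clip(s, 0.0, contour.total_length)
    cum = contour._cumlen
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(contour._seglen) - 1)
    # skip zero-length segments
    while np.any(contour._seglen[idx] == 0):
        idx = np.where((contour._seglen[idx] == 0) & (idx < len(contour._seglen) - 1), idx + 1, idx)
        if np.all(contour._seglen[np.minimum(idx, len(contour._seglen) - 1)] > 0):
            break
    frac = (s - cum[idx]) / np.where(contour._seglen[idx] > 0, contour._seglen[idx], 1.0)
    frac = np.clip(frac, 0.0, 1.0)
    pt = contour.vertices[idx] + frac[:, None] * contour._seg[idx]
    tan = contour._seg[idx] / np.where(contour._seglen[idx] > 0, contour._seglen[idx], 1.0)[:, None]
    # left normal of direction (dx, dy) is (-dy, dx) in cross-product terms
    left_normal = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
    sign = 1.0 if contour.side_convention == "left" else -1.0
    return pt, tan, sign * left_normal


def closest_approach_many(contour: MembraneContour, points: np.ndarray):
    """Vectorized closest approach of many points to one contour.

    Returns ``(proximity, foot_arc, side)`` arrays.  ``side`` is
    ``SIDE_CYTOPLASM`` / ``SIDE_EXTRACELLULAR`` per the contour's
    convention, or ``SIDE_ON_MEMBRANE`` at distance ~0.

    At a vertex foot shared by two segments the side is decided by the sum
    of the normalized cross products of both adjacent segments (angle
    bisector rule), which is stable at convex/concave corners.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    v = contour.vertices
    seg = contour._seg
    seglen2 = contour._seglen**2
    ok = contour._seglen > 0
    a = v[:-1][ok]
    seg = seg[ok]
    seglen2 = seglen2[ok]
    cum = contour._cumlen[:-1][ok]
    slen = contour._seglen[ok]

    # (M, S) projections
    d = pts[:, None, :] - a[None, :, :]
    t = np.clip((d * seg[None, :, :]).sum(-1) / seglen2[None, :], 0.0, 1.0)
    foot = a[None, :, :] + t[:, :, None] * seg[None, :, :]
    diff = pts[:, None, :] - foot
    dist2 = (diff**2).sum(-1)
    imin = np.argmin(dist2, axis=1)
    m = np.arange(pts.shape[0])
    prox = np.sqrt(dist2[m, imin])
    foot_arc = cum[imin] + t[m, imin] * slen[imin]

    # sidedness via cross product of the nearest segment; at clipped feet
    # (vertex hits) blend with the adjacent segment sharing that vertex
    def _cross(i_seg):
        dd = pts - a[i_seg]
        return seg[i_seg, 0] * dd[:, 1] - seg[i_seg, 1] * dd[:, 0]

    cr = _cross(imin) / slen[imin]
    tmin = t[m, imin]
    at_end = (tmin >= 1.0 - 1e-12) & (imin < len(slen) - 1)
    at_start = (tmin <= 1e-12) & (imin > 0)
    nb = np.where(at_end, np.minimum(imin + 1, len(slen) - 1),
                  np.where(at_start, np.maximum(imin - 1, 0), imin))
    shared = nb != imin
    if np.any(shared):
        cr_nb = _cross(nb) / slen[nb]
        cr = np.where(shared, cr + cr_nb, cr)

    sign = 1.0 if contour.side_convention == "left" else -1.0
    side = np.where(prox <= 1e-9, SIDE_ON_MEMBRANE,
                    np.where(sign * cr > 0, SIDE_CYTOPLASM, SIDE_EXTRACELLULAR))
    return prox, foot_arc, side.astype(int)


def closest_approach(contour: MembraneContour, point) -> tuple[float, float, int]:
    """Closest approach of a single point: ``(proximity_nm, foot_arc_nm, side)``."""
    prox, foot, side = closest_approach_many(contour, np.asarray(point, dtype=float)[None, :])
    return float(prox[0]), float(foot[0]), int(side[0])


def nearest_contour(annotation: MicrographAnnotation, points: np.ndarray):
    """Closest approach over all contours of an annotation.

    Returns ``(contour_index, proximity, foot_arc, side)`` arrays, taking
    for each point the contour with the smallest proximity.
    """
    if not annotation.contours:
        raise ValueError("annotation has no contours")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    best = None
    for ci, c in enumerate(annotation.contours):
        prox, foot, side = closest_approach_many(c, pts)
        if best is None:
            best = [np.full(len(pts), ci), prox, foot, side]
        else:
            take = prox < best[1]
            best[0] = np.where(take, ci, best[0])
            best[1] = np.where(take, prox, best[1])
            best[2] = np.where(take, foot, best[2])
            best[3] = np.where(take, side, best[3])
    return best[0], best[1], best[2], best[3]
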