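"""Labeling resolution: measured and simulated tag-to-membrane distances.

A membrane-anchored tag holds its particle some distance from the target
protein.  The tag can adopt length states between 7 and 18 nm (the fully
extended co-linear arrangement is 22 nm), and its orientation relative to
the membrane normal is constrained by the membrane itself.  The detected
position in a 70-nm EM section therefore scatters around the anchor; the
spread of the in-plane perpendicular distance distribution *is* the
labeling resolution.

``simulate_detected_distances`` models one detection: draw a tag length,
draw an orientation (perpendicular, hemisphere-uniform, or uniform within
a cone about the membrane normal — all excluded from the membrane
half-space), place the particle in 3-D on a flat membrane, keep it if its
center falls inside a randomly positioned section, and record the
perpendicular distance of the projected center to the membrane trace.

The default model (continuous uniform lengths 7–18 nm, cone half-angle
35°) is calibrated so the simulated spread matches the ~10 nm
full-width-at-half-maximum labeling resolution; see docs/methods.md for
the closed form FWHM = 11·sqrt(cos(half-angle)) nm behind that choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .annotations import SIDE_CYTOPLASM, MicrographAnnotation, nearest_contour

__all__ = [
    "TagGeometryModel",
    "DistanceSample",
    "SnrRecord",
    "measure_distances",
    "simulate_detected_distances",
    "fwhm",
    "particle_snr",
]

ORIENTATION_LAWS = ("perpendicular", "hemisphere-uniform", "cone")


@dataclass(frozen=True)
class TagGeometryModel:
    """Geometry of the tag linking a membrane anchor to its particle.

    ``n_length_states=None`` means a continuous uniform length law on
    [length_min_nm, length_max_nm]; an integer gives that many evenly
    spaced discrete states.  ``cone_half_angle_deg`` only applies to the
    "cone" orientation law.
    """

    length_min_nm: float = 7.0
    length_max_nm: float = 18.0
    length_max_theoretical_nm: float = 22.0
    n_length_states: int | None = None
    orientation_law: str = "cone"
    cone_half_angle_deg: float = 35.0
    section_thickness_nm: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.length_min_nm <= self.length_max_nm <= self.length_max_theoretical_nm):
            raise ValueError("require 0 < length_min <= length_max <= length_max_theoretical")
        if self.orientation_law not in ORIENTATION_LAWS:
            raise ValueError(f"orientation_law must be one of {ORIENTATION_LAWS}")
        if self.n_length_states is not None and self.n_length_states < 1:
            raise ValueError("n_length_states must be >= 1 (or None for continuous)")
        if self.section_thickness_nm <= 0:
            raise ValueError("section_thickness_nm must be positive")

    def sample_lengths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.n_length_states is None:
            return rng.uniform(self.length_min_nm, self.length_max_nm, n)
        if self.n_length_states == 1:
            states = np.array([0.5 * (self.length_min_nm + self.length_max_nm)])
        else:
            states = np.linspace(self.length_min_nm, self.length_max_nm, self.n_length_states)
        return rng.choice(states, size=n)

    def sample_axis_cosines(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """cos(angle to membrane normal), uniform in solid angle within the law."""
        if self.orientation_law == "perpendicular":
            return np.ones(n)
        if self.orientation_law == "hemisphere-uniform":
            return rng.uniform(0.0, 1.0, n)
        cmin = np.cos(np.radians(self.cone_half_angle_deg))
        return rng.uniform(cmin, 1.0, n)

    def metadata(self) -> dict:
        return {
            "length_min_nm": self.length_min_nm,
            "length_max_nm": self.length_max_nm,
            "length_max_theoretical_nm": self.length_max_theoretical_nm,
            "n_length_states": self.n_length_states if self.n_length_states else "continuous",
            "orientation_law": self.orientation_law,
            "cone_half_angle_deg": self.cone_half_angle_deg,
            "section_thickness_nm": self.section_thickness_nm,
        }


@dataclass
class DistanceSample:
    """A sample of tag-to-membrane distances with standard summaries."""

    distances: np.ndarray
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")

    @property
    def n(self) -> int:
        return self.distances.size

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    def fwhm(self, bandwidth=None) -> float:
        return fwhm(self.distances, bandwidth)


@dataclass
class SnrRecord:
    particle_id: int
    signal: float
    background_mean: float
    background_sd: float
    snr: float | None


def measure_distances(annotations: list[MicrographAnnotation]) -> DistanceSample:
    """Perpendicular particle-to-membrane distances, cytoplasmic side only.

    Uses the closest approach to the nearest contour.  Extracellular-side
    particles are excluded; the count of exclusions is reported.
    """
    dists = []
    excluded = 0
    any_contour = False
    for ann in annotations:
        if not ann.contours:
            continue
        any_contour = True
        pts = ann.particle_array()
        if len(pts) == 0:
            continue
        _, prox, _, side = nearest_contour(ann, pts)
        keep = side >= 0
        dists.append(prox[keep])
        excluded += int((~keep).sum())
    if not any_contour:
        raise ValueError("no contours in any annotation")
    d = np.concatenate(dists) if dists else np.empty(0)
    return DistanceSample(d, n_excluded=excluded, meta={"source": "measured"})


def simulate_detected_distances(model: TagGeometryModel, n_draws: int,
                                seed: int | np.random.Generator = 0) -> DistanceSample:
    """Monte-Carlo detected-distance sample under a tag geometry model.

    Geometry: membrane is the plane x = 0 (cytoplasm x > 0); the section
    is a slab of the model thickness along y, positioned uniformly at
    random relative to each anchor; viewing is along y so the in-plane
    perpendicular distance of an accepted particle is its x coordinate.
    Acceptance is by particle-center inclusion.  Deterministic for a
    fixed seed; exactly ``n_draws`` accepted detections are returned.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = model.section_thickness_nm
    out = np.empty(0)
    n_total = 0
    while out.size < n_draws:
        n = max(int((n_draws - out.size) * 1.5) + 16, 32)
        L = model.sample_lengths(rng, n)
        c = model.sample_axis_cosines(rng, n)
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        sin_t = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
        x = L * c                      # perpendicular offset from membrane
        y = L * sin_t * np.cos(phi)    # along the sectioning axis
        # anchor position along the slab axis, wide enough to cover reach
        y_anchor = rng.uniform(-model.length_max_theoretical_nm,
                               t + model.length_max_theoretical_nm, n)
        y_p = y_anchor + y
        accept = (y_p >= 0.0) & (y_p < t) & (x >= 0.0)
        n_total += n
        out = np.concatenate([out, x[accept]])
    return DistanceSample(out[:n_draws], meta={
        "n_draws": n_draws, "n_proposed": n_total, **model.metadata()})


def fwhm(values, bandwidth=None, grid_size: int = 2048) -> float:
    """Full width at half maximum of a kernel-density estimate.

    ``bandwidth`` follows :class:`scipy.stats.gaussian_kde` conventions
    (default: Silverman's rule).  The width runs between the outermost
    half-maximum crossings, linearly interpolated; the evaluation grid is
    padded by three bandwidths so edge modes are resolved.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError("need >= 50 values for a stable density estimate")
    if np.ptp(x) == 0:
        warnings.warn("all values identical; FWHM is 0")
        return 0.0
    kde = gaussian_kde(x, bw_method=bandwidth if bandwidth is not None else "silverman")
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = kde(grid)
    half = dens.max() / 2.0
    above = dens >= half
    idx = np.where(above)[0]
    i0, i1 = idx[0], idx[-1]

    def _interp(i_lo, i_hi):
        # linear crossing between grid[i_lo] (below) and grid[i_hi] (above)
        y0, y1 = dens[i_lo], dens[i_hi]
        if y1 == y0:
            return grid[i_hi]
        f = (half - y0) / (y1 - y0)
        return grid[i_lo] + f * (grid[i_hi] - grid[i_lo])

    left = grid[i0] if i0 == 0 else _interp(i0 - 1, i0)
    right = grid[i1] if i1 == len(grid) - 1 else _interp(i1 + 1, i1)
    return float(right - left)


def particle_snr(patch: np.ndarray, center: tuple[float, float],
                 r_signal: float, r_bg_inner: float, r_bg_outer: float,
                 particle_id: int = 0) -> SnrRecord:
    """Per-particle signal-to-noise ratio on an image patch.

    Signal is the mean intensity in a disc of radius ``r_signal`` (px)
    around ``center``; background mean and SD come from the annulus
    ``r_bg_inner..r_bg_outer``.  SNR = |signal - bg mean| / bg SD, reported
    as None (missing) when the annulus SD is zero.  Defaults elsewhere use
    r_signal = 3.5 nm (half the 7 nm particle) and a 7–14 nm annulus,
    converted to pixels by the frame calibration.
    """
    if not (0 < r_signal < r_bg_inner < r_bg_outer):
        raise ValueError("require 0 < r_signal < r_bg_inner < r_bg_outer")
    cy, cx = center[1], center[0]
    h, w = patch.shape
    if (cx - r_bg_outer < -0.5 or cx + r_bg_outer > w - 0.5
            or cy - r_bg_outer < -0.5 or cy + r_bg_outer > h - 0.5):
        raise ValueError("background annulus extends outside the patch")
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx - cx, yy - cy)
    disc = rr <= r_signal
    annulus = (rr >= r_bg_inner) & (rr <= r_bg_outer)
    if disc.sum() == 0 or annulus.sum() < 2:
        raise ValueError("empty disc or annulus; radii too small for pixel grid")
    signal = float(patch[disc].mean())
    bg_mean = float(patch[annulus].mean())
    bg_sd = float(patch[annulus].std(ddof=1))
    snr = abs(signal - bg_mean) / bg_sd if bg_sd > 0 else None
    return SnrRecord(particle_id, signal, bg_mean, bg_sd, snr)
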