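"""Synthetic annotated scenes and image stacks with known ground truth.

``generate_scene`` emulates a segmented plasma-membrane profile crossing a
micrograph, with semicircular coated-pit invaginations, volumetric
particles placed by a Poisson law at configurable per-region densities
(count mean = density x area x section thickness), and membrane-anchored
particles displaced from arc anchors by a tag-geometry draw toward the
cytoplasmic side.  ``generate_kinetics_stack`` emulates two-channel
live-cell spot stacks whose second channel steps up at a stimulus onset.

These are annotation-level (and intensity-level) emulations for testing
the analysis stages; no electron-microscope texture is synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .annotations import (
    ImageFrame,
    MembraneContour,
    MicrographAnnotation,
    Particle,
    point_at_arc,
)
from .density import COMPARTMENTS, region_polygons
from .resolution import TagGeometryModel

__all__ = [
    "SceneConfig",
    "generate_scene",
    "generate_kinetics_stack",
    "PAPER_CYTOPLASM_DENSITY",
    "PAPER_COAT_DENSITY",
]

# measured density regime emulated by the default scene (particles/um^3)
PAPER_CYTOPLASM_DENSITY = 72.5
PAPER_COAT_DENSITY = 1308.6

_MAX_PARTICLES = 1_000_000


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic micrograph.

    Densities are particles/um^3; anchor rates are particles per nm of
    arc.  ``membrane_y_frac`` sets the membrane's vertical position as a
    fraction of frame height (jittered uniformly by ``membrane_jitter_frac``
    so ensembles of scenes vary); the pit radius default of 50 nm gives
    the canonical 100-nm-diameter pit.
    """

    width_px: int = 1024
    height_px: int = 768
    nm_per_px: float = 2.0
    section_thickness_nm: float = 70.0
    membrane_y_frac: float = 0.45
    membrane_jitter_frac: float = 0.0
    cytoplasm_density: float = PAPER_CYTOPLASM_DENSITY
    membrane_density: float = PAPER_CYTOPLASM_DENSITY
    coat_density: float = PAPER_COAT_DENSITY
    n_pits: int = 3
    pit_radius_nm: float = 50.0
    tag_model: TagGeometryModel | None = None
    distal_tag_model: TagGeometryModel | None = None
    anchored_rate_pit_per_nm: float = 0.0
    anchored_rate_distal_per_nm: float = 0.0
    condition: str = "synthetic"
    experiment_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cytoplasm_density", "membrane_density", "coat_density",
                     "anchored_rate_pit_per_nm", "anchored_rate_distal_per_nm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pit_radius_nm <= 0:
            raise ValueError("pit_radius_nm must be positive")
        if self.n_pits < 0:
            raise ValueError("n_pits must be >= 0")


# Pit-to-flat fillet radius: at least the proximal-zone width, so the
# nearest-foot map is one-to-one across the whole 50-nm band (and a fortiori
# for anchored tags reaching at most 22 nm); the coated band is then exactly
# the half-annulus of the pit arc.
FILLET_RADIUS_NM = 50.0


def _build_membrane(cfg: SceneConfig, rng: np.random.Generator,
                    n_arc_segments: int = 64):
    """Membrane polyline spanning the frame with smooth pit invaginations.

    Each pit is a semicircle of the configured radius, joined to the flat
    membrane by tangent-continuous quarter-circle fillets (radius 25 nm),
    as segmented membranes have no sharp corners.  Returns the contour
    plus per-pit (s_start, s_end) arc intervals bracketing the semicircle
    proper.  Cytoplasm is below the membrane (larger y), the 'left' side
    of the left-to-right polyline in raster coordinates.
    """
    w = cfg.width_px * cfg.nm_per_px
    h = cfg.height_px * cfg.nm_per_px
    y0 = cfg.membrane_y_frac * h
    if cfg.membrane_jitter_frac > 0:
        y0 += rng.uniform(-1, 1) * cfg.membrane_jitter_frac * h
    r = cfg.pit_radius_nm
    rho = FILLET_RADIUS_NM
    half_span = r + rho  # pit footprint half-width on the flat

    margin = half_span + 2.0 * r + 20.0
    min_sep = 2.0 * half_span + r
    centers: list[float] = []
    if cfg.n_pits > 0:
        usable = w - 2 * margin
        if usable < cfg.n_pits * min_sep:
            raise ValueError("frame too small for the requested number of pits")
        for _ in range(200 * cfg.n_pits):
            c = rng.uniform(margin, w - margin)
            if all(abs(c - o) > min_sep for o in centers):
                centers.append(c)
            if len(centers) == cfg.n_pits:
                break
        else:
            raise ValueError("could not place non-overlapping pits")
        centers.sort()

    n_fillet = max(n_arc_segments // 4, 8)
    verts = [(0.0, y0)]
    pit_vertex_spans = []
    for c in centers:
        # entry fillet: concave quarter arc from the flat tangency
        # (c - r - rho, y0) to the pit tangency (c - r, y0 + rho); its
        # center sits at (c - r - rho, y0 + rho)
        fx, fy = c - r - rho, y0 + rho
        verts.append((fx, y0))
        for t in np.linspace(0.0, np.pi / 2.0, n_fillet + 1)[1:]:
            verts.append((fx + rho * np.sin(t), fy - rho * np.cos(t)))
        i_start = len(verts) - 1
        # pit semicircle, center (c, y0 + rho), from (c - r, y0 + rho)
        # through the apex (c, y0 + rho + r) to (c + r, y0 + rho)
        phis = np.linspace(0.0, np.pi, n_arc_segments + 1)[1:]
        for phi in phis:
            verts.append((c - r * np.cos(phi), y0 + rho + r * np.sin(phi)))
        i_end = len(verts) - 1
        pit_vertex_spans.append((i_start, i_end))
        # exit fillet, mirror of the entry
        gx, gy = c + r + rho, y0 + rho
        for t in np.linspace(np.pi / 2.0, 0.0, n_fillet + 1)[1:]:
            verts.append((gx - rho * np.sin(t), gy - rho * np.cos(t)))
    verts.append((w, y0))

    contour = MembraneContour(np.asarray(verts), side_convention="left")
    cum = contour._cumlen
    pit_intervals = [(float(cum[i0]), float(cum[i1])) for i0, i1 in pit_vertex_spans]
    return contour, pit_intervals


def _sample_in_polygon(poly, rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform points inside a shapely geometry by bounding-box rejection."""
    if n == 0 or poly.is_empty or poly.area == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = []
    need = n
    frac = max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    while need > 0:
        m = int(need / frac * 1.2) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(poly, xs, ys)
        pts = np.column_stack([xs[inside], ys[inside]])
        out.append(pts[:need])
        need -= min(len(pts), need)
    return np.concatenate(out)


def _sample_arc_positions(intervals, rng: np.random.Generator, rate_per_nm: float):
    """Poisson number of anchors, uniform over a union of arc intervals."""
    lens = np.array([b - a for a, b in intervals], dtype=float)
    total = lens.sum()
    if total <= 0 or rate_per_nm <= 0:
        return np.empty(0)
    n = rng.poisson(rate_per_nm * total)
    if n == 0:
        return np.empty(0)
    picks = rng.choice(len(intervals), size=n, p=lens / total)
    u = rng.uniform(0.0, 1.0, n)
    return np.array([intervals[i][0] + u[k] * lens[i] for k, i in enumerate(picks)])


def generate_scene(cfg: SceneConfig,
                   rng: np.random.Generator | None = None):
    """Generate one annotated micrograph and its ground truth.

    Returns ``(MicrographAnnotation, pandas.DataFrame)``.  The ground
    truth has one row per particle: true region at generation time,
    anchored flag, anchor arc position, tag length, displacement and
    conformation class for anchored particles.  Fixed config seed gives
    identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    frame = ImageFrame(cfg.width_px, cfg.height_px, cfg.nm_per_px,
                       cfg.section_thickness_nm)
    contour, pit_intervals = _build_membrane(cfg, rng)
    contour = MembraneContour(
        contour.vertices,
        coat_intervals=pit_intervals,
        pit_marks=pit_intervals[0] if len(pit_intervals) == 1 else None,
        side_convention="left",
    )
    skeleton = MicrographAnnotation(frame, [contour], [],
                                    condition=cfg.condition,
                                    experiment_id=cfg.experiment_id)
    polys = region_polygons(skeleton)

    t_nm = cfg.section_thickness_nm
    band = polys["membrane_proximal_band"]
    band_density_max = max(cfg.membrane_density, cfg.coat_density)
    expected_total = (cfg.cytoplasm_density * polys["cytoplasm"].area
                      + band_density_max * band.area) * t_nm * 1e-9
    if expected_total > _MAX_PARTICLES:
        raise ValueError(
            f"configured densities imply ~{expected_total:.0f} particles per image; "
            f"the limit is {_MAX_PARTICLES}. Reduce densities or frame size."
        )

    particles: list[Particle] = []
    truth_rows: list[dict] = []

    def _add_volumetric(pts, regions):
        for (x, y), c in zip(pts, regions):
            truth_rows.append({"particle": len(particles), "x_nm": x, "y_nm": y,
                               "region": c, "anchored": False,
                               "anchor_s_nm": np.nan, "tag_length_nm": np.nan,
                               "displacement_nm": np.nan, "conformation": ""})
            particles.append(Particle((float(x), float(y))))

    n_cyto = rng.poisson(cfg.cytoplasm_density * polys["cytoplasm"].area * t_nm * 1e-9)
    pts = _sample_in_polygon(polys["cytoplasm"], rng, n_cyto)
    _add_volumetric(pts, ["cytoplasm"] * len(pts))

    # band particles: homogeneous Poisson at the larger band density, thinned
    # per point by its *classified* sub-compartment — exact Poisson counts at
    # each density, and placement consistent with the classifier by
    # construction (no coated-area computation needed)
    if band_density_max > 0 and band.area > 0:
        from .density import classify_points as _classify

        n_cand = rng.poisson(band_density_max * band.area * t_nm * 1e-9)
        cand = _sample_in_polygon(band, rng, n_cand)
        if len(cand):
            labels = _classify(skeleton, cand)
            keep_p = {"membrane_proximal_uncoated":
                      cfg.membrane_density / band_density_max,
                      "membrane_proximal_coated":
                      cfg.coat_density / band_density_max}
            u = rng.uniform(0.0, 1.0, len(cand))
            sel = [i for i, lab in enumerate(labels)
                   if lab in keep_p and u[i] < keep_p[lab]]
            _add_volumetric(cand[sel], [labels[i] for i in sel])

    # membrane-anchored particles: coat/pit arcs vs distal (uncoated) arcs
    total_len = contour.total_length
    uncoated: list[tuple[float, float]] = []
    prev = 0.0
    for a, b in pit_intervals:
        if a > prev:
            uncoated.append((prev, a))
        prev = b
    if total_len > prev:
        uncoated.append((prev, total_len))

    pit_model = cfg.tag_model or TagGeometryModel()
    distal_model = cfg.distal_tag_model or pit_model
    w_nm, h_nm = frame.width_nm, frame.height_nm
    for intervals, rate, model, conf in (
        (pit_intervals, cfg.anchored_rate_pit_per_nm, pit_model, "extended"),
        (uncoated, cfg.anchored_rate_distal_per_nm, distal_model, "kinked"),
    ):
        s_anchor = _sample_arc_positions(intervals, rng, rate)
        if len(s_anchor) == 0:
            continue
        pt, _, normal = point_at_arc(contour, s_anchor)
        L = model.sample_lengths(rng, len(s_anchor))
        c_ax = model.sample_axis_cosines(rng, len(s_anchor))
        d = L * c_ax
        pos = pt + d[:, None] * normal
        region = ("membrane_proximal_coated" if conf == "extended"
                  else "membrane_proximal_uncoated")
        for k in range(len(s_anchor)):
            x, y = pos[k]
            if not (0 <= x <= w_nm and 0 <= y <= h_nm):
                continue  # rare edge clip; anchors sit well inside by construction
            truth_rows.append({"particle": len(particles), "x_nm": x, "y_nm": y,
                               "region": region, "anchored": True,
                               "anchor_s_nm": s_anchor[k], "tag_length_nm": L[k],
                               "displacement_nm": d[k], "conformation": conf})
            particles.append(Particle((float(x), float(y))))

    annotation = MicrographAnnotation(frame, [contour], particles,
                                      condition=cfg.condition,
                                      experiment_id=cfg.experiment_id)
    truth = pd.DataFrame(truth_rows, columns=[
        "particle", "x_nm", "y_nm", "region", "anchored", "anchor_s_nm",
        "tag_length_nm", "displacement_nm", "conformation"])
    return annotation, truth


def generate_grid_matched_scene(rng: np.random.Generator,
                                width_px: int = 1024, height_px: int = 512,
                                nm_per_px: float = 1.0,
                                section_thickness_nm: float = 70.0,
                                n_pits: int = 2,
                                pit_radius_nm: float = 50.0) -> MicrographAnnotation:
    """Membrane geometry whose randomness is matched to the stereology grid.

    Point-counting with a fixed interior grid estimates area fractions
    without bias only when the scene geometry is translated uniformly over
    whole grid periods: here the membrane height is uniform over two
    vertical line spacings and each pit center is uniform over exactly one
    horizontal spacing (jittered slots), with every coat band inside the
    lattice-covered window and slots spaced so that coat bands of adjacent
    pits can never overlap (overlaps would break the translation-averaging
    identity on the intersection terms).  Used for null-calibration
    ensembles of the RLI test; returns an annotation without particles.
    """
    w = width_px * nm_per_px
    h = height_px * nm_per_px
    period_x = w / 7.0
    period_y = h / 5.0
    r = pit_radius_nm
    y0 = 0.45 * h + rng.uniform(-1, 1) * period_y

    band_reach = r + 50.0  # coat band half-extent in x around a pit center
    base0 = period_x / 2.0 + band_reach
    slot_spacing = 2.0 * band_reach + period_x + 5.0  # coat bands never overlap
    if n_pits > 0:
        last = base0 + (n_pits - 1) * slot_spacing + period_x
        if last + band_reach > w - period_x / 2.0:
            raise ValueError("frame too narrow for grid-matched pit slots")
        centers = sorted(base0 + k * slot_spacing + rng.uniform(0.0, period_x)
                         for k in range(n_pits))
    else:
        centers = []

    verts = [(0.0, y0)]
    spans = []
    for c in centers:
        verts.append((c - r, y0))
        i0 = len(verts) - 1
        for phi in np.linspace(0.0, np.pi, 65)[1:]:
            verts.append((c - r * np.cos(phi), y0 + r * np.sin(phi)))
        spans.append((i0, len(verts) - 1))
    verts.append((w, y0))
    contour = MembraneContour(np.asarray(verts), side_convention="left")
    cum = contour._cumlen
    ivals = [(float(cum[a]), float(cum[b])) for a, b in spans]
    contour = MembraneContour(contour.vertices, coat_intervals=ivals,
                              side_convention="left")
    frame = ImageFrame(width_px, height_px, nm_per_px, section_thickness_nm)
    return MicrographAnnotation(frame, [contour], [], condition="null",
                                experiment_id="grid-matched")


# ---------------------------------------------------------------------------
# kinetics stacks


def generate_kinetics_stack(
    n_frames: int = 40,
    n_spots: int = 12,
    onset_frame: int = 20,
    response_amplitude: float = 2.0,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (128, 128),
    background: tuple[float, float] = (20.0, 10.0),
    spot_amplitude_ch1: float = 50.0,
    spot_sigma_px: float = 1.8,
):
    """Two-channel step-response spot stack plus ground truth.

    Channel 1 carries persistent Gaussian spots (reference channel);
    channel 2 shares the spot profile but its spot intensity steps from
    baseline to baseline + ``response_amplitude`` x profile at
    ``onset_frame``.  Both channels have non-zero background and additive
    Gaussian noise.  Returns ``(stack, truth)`` with stack shaped
    (n_frames, 2, H, W) float32 and truth holding spot centers, the onset
    frame, and the expected background-subtracted channel ratio step
    (= response_amplitude / spot_amplitude_ch1).
    """
    if not (0 < onset_frame < n_frames):
        raise ValueError("onset_frame must lie strictly inside the stack")
    if response_amplitude < 0:
        raise ValueError("response_amplitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = shape
    sep = max(int(np.ceil(8 * spot_sigma_px)), 12)
    capacity = max((h - 2 * sep) // sep, 0) * max((w - 2 * sep) // sep, 0)
    if n_spots > capacity:
        raise ValueError(f"{n_spots} spots exceed frame capacity ({capacity}) "
                         f"at separation {sep} px")

    centers: list[tuple[float, float]] = []
    for _ in range(2000):
        cy = rng.uniform(sep, h - sep)
        cx = rng.uniform(sep, w - sep)
        if all((cy - a) ** 2 + (cx - b) ** 2 > sep**2 for a, b in centers):
            centers.append((cy, cx))
        if len(centers) == n_spots:
            break
    else:
        raise ValueError("could not place well-separated spots")

    yy, xx = np.mgrid[0:h, 0:w]
    profile = np.zeros((h, w))
    for cy, cx in centers:
        profile += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spot_sigma_px**2))

    stack = np.empty((n_frames, 2, h, w), dtype=np.float32)
    for t in range(n_frames):
        ch1 = background[0] + spot_amplitude_ch1 * profile
        step = response_amplitude if t >= onset_frame else 0.0
        ch2 = background[1] + step * profile
        if noise_sd > 0:
            ch1 = ch1 + rng.normal(0.0, noise_sd, (h, w))
            ch2 = ch2 + rng.normal(0.0, noise_sd, (h, w))
        stack[t, 0] = ch1
        stack[t, 1] = ch2

    truth = {
        "centers": centers,
        "onset_frame": onset_frame,
        "expected_ratio_step": response_amplitude / spot_amplitude_ch1,
        "background": background,
    }
    return stack, truth
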