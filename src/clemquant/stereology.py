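"""Relative labeling intensity (RLI) by point-counting stereology.

Following the Mayhew–Lucocq approach, an 8 x 6 line grid is overlaid on
each micrograph with its outer lines on the image perimeter, giving
6 x 4 = 24 interior test points per image.  Each point is classified with
the same compartment rule used for particles; the pooled compartment
fractions, scaled to the total number of observed particles, give the
expected counts N_e.  RLI = observed / expected per compartment, and a
2 x 2 contingency table {observed, expected} x {cytoplasm, coated} is
tested with a Yates-continuity-corrected chi-squared statistic (df = 1).

``yates_chi2_2x2`` is written out explicitly (cell expectations from the
table margins, |O - E| reduced by 0.5 and clamped at zero) because the
statistic applied to an observed-vs-expected table *is* the quantity
reported; library contingency tests serve as an independent cross-check
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erfc

from .annotations import ImageFrame, MicrographAnnotation
from .density import ALL_REGIONS, COMPARTMENTS, PROXIMAL_ZONE_NM, RegionTally, classify_points

__all__ = [
    "GridSpec",
    "StereologyResult",
    "grid_points",
    "point_compartment_fractions",
    "expected_counts",
    "yates_chi2_2x2",
    "chi2_sf_df1",
    "rli_report",
]


@dataclass(frozen=True)
class GridSpec:
    """Line grid whose outer lines coincide with the image perimeter."""

    n_vertical_lines: int = 8
    n_horizontal_lines: int = 6

    @property
    def n_interior_points(self) -> int:
        return (self.n_vertical_lines - 2) * (self.n_horizontal_lines - 2)


DEFAULT_GRID = GridSpec()


@dataclass
class StereologyResult:
    """Observed vs expected counts, RLI, and the Yates chi-squared test."""

    experiment_id: str
    n_images: int
    observed: dict[str, int]
    expected: dict[str, float]
    rli: dict[str, float]
    chi2: float
    df: int
    p_value: float

    def to_frame(self) -> pd.DataFrame:
        row = {"experiment": self.experiment_id, "n_images": self.n_images}
        for c in COMPARTMENTS:
            row[f"obs_{c}"] = self.observed[c]
        row["obs_total"] = sum(self.observed[c] for c in COMPARTMENTS)
        for c in COMPARTMENTS:
            row[f"exp_{c}"] = self.expected[c]
        row["exp_total"] = sum(self.expected[c] for c in COMPARTMENTS)
        for c in COMPARTMENTS:
            row[f"rli_{c}"] = self.rli[c]
        row["chi2"] = self.chi2
        row["df"] = self.df
        row["p_value"] = self.p_value
        return pd.DataFrame([row])


def grid_points(frame: ImageFrame, grid: GridSpec = DEFAULT_GRID) -> np.ndarray:
    """Interior grid intersections in nm, shape (24, 2) for the default grid.

    Vertical lines sit at x = k W/(nv-1), horizontal at y = j H/(nh-1);
    the outer lines coincide with the perimeter and are excluded.
    """
    w, h = frame.width_nm, frame.height_nm
    xs = np.arange(1, grid.n_vertical_lines - 1) * w / (grid.n_vertical_lines - 1)
    ys = np.arange(1, grid.n_horizontal_lines - 1) * h / (grid.n_horizontal_lines - 1)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def point_compartment_fractions(annotations: list[MicrographAnnotation],
                                grid: GridSpec = DEFAULT_GRID,
                                zone_nm: float = PROXIMAL_ZONE_NM) -> dict[str, float]:
    """Fraction of grid points per compartment, pooled over images.

    Fractions over all four regions (including extracellular) sum to 1.
    """
    if not annotations:
        raise ValueError("need >= 1 image")
    counts = {c: 0 for c in ALL_REGIONS}
    for ann in annotations:
        pts = grid_points(ann.frame, grid)
        for lab in classify_points(ann, pts, zone_nm):
            counts[lab] += 1
    total = sum(counts.values())
    return {c: counts[c] / total for c in ALL_REGIONS}


def expected_counts(fractions: dict[str, float], total_observed: float) -> dict[str, float]:
    """Scale intracellular point fractions to the observed particle total.

    Particles are only tallied in intracellular compartments, so the
    fractions are renormalized over those before scaling; the expected
    counts then sum exactly to ``total_observed``.
    """
    if total_observed < 0:
        raise ValueError("total observed must be >= 0")
    intra = sum(fractions.get(c, 0.0) for c in COMPARTMENTS)
    if intra <= 0:
        raise ValueError("no intracellular grid points to scale")
    return {c: fractions.get(c, 0.0) / intra * total_observed for c in COMPARTMENTS}


def yates_chi2_2x2(table) -> float:
    """Yates-corrected chi-squared statistic of a 2 x 2 table.

    Cell expectations come from the row/column margins; each cell
    contributes ``max(|O - E| - 0.5, 0)^2 / E``.  The rows may be an
    observed-count row and a margin-scaled expected row (as in an RLI
    report); the statistic is symmetric under row and column swaps.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2 x 2")
    if np.any(t < 0):
        raise ValueError("cells must be >= 0")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        bad = "row" if np.any(rows == 0) else "column"
        raise ValueError(f"degenerate {bad} margin (sums to zero)")
    e = np.outer(rows, cols) / t.sum()
    adj = np.maximum(np.abs(t - e) - 0.5, 0.0)
    return float((adj**2 / e).sum())


def chi2_sf_df1(x: float) -> float:
    """Upper-tail probability of chi-squared with 1 df, via erfc."""
    if x < 0:
        raise ValueError("chi-squared statistic must be >= 0")
    return float(erfc(np.sqrt(x / 2.0)))


def rli_report(tally: RegionTally, fractions: dict[str, float]) -> StereologyResult:
    """RLI per compartment plus the cytoplasm-vs-coated Yates test.

    ``tally`` and ``fractions`` must come from the same experiment.  RLI is
    observed/expected, reported as NaN where the expected count is zero.
    """
    expected = expected_counts(fractions, tally.total)
    rli = {}
    for c in COMPARTMENTS:
        e = expected[c]
        rli[c] = tally.counts[c] / e if e > 0 else float("nan")
    table = [
        [tally.counts["cytoplasm"], tally.counts["membrane_proximal_coated"]],
        [expected["cytoplasm"], expected["membrane_proximal_coated"]],
    ]
    chi2 = yates_chi2_2x2(table)
    return StereologyResult(
        experiment_id=tally.experiment_id,
        n_images=tally.n_images,
        observed={c: tally.counts[c] for c in COMPARTMENTS},
        expected=expected,
        rli=rli,
        chi2=chi2,
        df=1,
        p_value=chi2_sf_df1(chi2),
    )


def grid_window(frame: ImageFrame, grid: GridSpec = DEFAULT_GRID):
    """Rectangle covered by the interior grid lattice at density 1/cell.

    Extends half a line spacing beyond the outermost interior points;
    particle-placement laws restricted to this window are what the grid
    fractions estimate without boundary bias.
    """
    w, h = frame.width_nm, frame.height_nm
    sx = w / (grid.n_vertical_lines - 1)
    sy = h / (grid.n_horizontal_lines - 1)
    return sx / 2.0, w - sx / 2.0, sy / 2.0, h - sy / 2.0


def simulate_null_experiments(n_experiments: int,
                              designs=((26, 165), (16, 66), (8, 46), (5, 10)),
                              seed: int | np.random.Generator = 0,
                              grid: GridSpec = DEFAULT_GRID,
                              zone_nm: float = PROXIMAL_ZONE_NM) -> pd.DataFrame:
    """Null-calibration ensemble for the RLI chi-squared test.

    Each simulated experiment draws ``n_images`` fresh grid-matched
    membrane geometries (see
    :func:`clemquant.synthetic.generate_grid_matched_scene`) and places
    ``n_particles`` intracellular particles uniformly over the grid
    window — the same spatial law the grid points sample — then runs the
    full observed-vs-expected pipeline.  ``designs`` cycles through
    ``(n_images, n_particles)`` experiment sizes.  Returns one row per
    experiment with observed/expected/grid counts, chi2 and p (chi2/p are
    NaN where a margin is degenerate, e.g. no coated point at all).

    Under this matched null the expected counts are unbiased, so the
    ensemble RLI converges to 1; the chi-squared rejection rate is a
    property of the test itself at the given design sizes (see
    docs/methods.md for why it is conservative when grid points outnumber
    particles).
    """
    from .density import classify_points as _classify
    from .synthetic import generate_grid_matched_scene

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # nominal intracellular fraction of the grid window, used only to set the
    # rain intensity so the expected observed total matches the design size
    f_intra = 0.53
    rows = []
    for e in range(n_experiments):
        n_images, n_particles = designs[e % len(designs)]
        gcount = {c: 0 for c in COMPARTMENTS}
        obs = {c: 0 for c in COMPARTMENTS}
        lam = n_particles / (n_images * f_intra)
        for _ in range(n_images):
            ann = generate_grid_matched_scene(rng)
            x0, x1, y0, y1 = grid_window(ann.frame, grid)
            gp = grid_points(ann.frame, grid)
            for lab in _classify(ann, gp, zone_nm):
                if lab in gcount:
                    gcount[lab] += 1
            # particles rain uniformly over the window; intracellular ones
            # are observed (no per-image conditioning, which would bias the
            # compartment fractions relative to the grid's)
            m = rng.poisson(lam)
            if m:
                pts = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
                for lab in _classify(ann, pts, zone_nm):
                    if lab in obs:
                        obs[lab] += 1
        tot = sum(obs.values())
        gtot = sum(gcount.values())
        exp = {c: gcount[c] / gtot * tot for c in COMPARTMENTS}
        try:
            chi2 = yates_chi2_2x2([[obs["cytoplasm"], obs["membrane_proximal_coated"]],
                                   [exp["cytoplasm"], exp["membrane_proximal_coated"]]])
            p = chi2_sf_df1(chi2)
        except ValueError:
            chi2, p = np.nan, np.nan
        row = {"experiment": e, "n_images": n_images, "n_particles": n_particles,
               "chi2": chi2, "p_value": p}
        for c in COMPARTMENTS:
            row[f"obs_{c}"] = obs[c]
            row[f"exp_{c}"] = exp[c]
            row[f"grid_{c}"] = gcount[c]
        rows.append(row)
    return pd.DataFrame(rows)


def pooled_rli(null_table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Ensemble RLI per compartment with a replicate SE.

    Per-experiment RLI divides by an expected count whose denominator (the
    experiment's own intracellular grid total) is a small, clustered
    sample, so the ratio is biased at finite grid size (Jensen); for the
    calibration summary the consistent estimator scales each experiment's
    observed total by the *globally pooled* grid fractions instead.  SE
    comes from the across-experiment scatter of obs - expected.
    """
    out = {}
    n = len(null_table)
    gtot = sum(float(null_table[f"grid_{c}"].sum()) for c in COMPARTMENTS)
    totals = sum(null_table[f"obs_{c}"] for c in COMPARTMENTS).to_numpy(float)
    for c in COMPARTMENTS:
        frac = float(null_table[f"grid_{c}"].sum()) / gtot
        exp = totals * frac
        d = null_table[f"obs_{c}"].to_numpy(float) - exp
        me = exp.mean()
        out[c] = (1.0 + d.mean() / me, d.std(ddof=1) / np.sqrt(n) / me)
    return out


def stereology_report(annotations: list[MicrographAnnotation],
                      experiment_id: str | None = None,
                      grid: GridSpec = DEFAULT_GRID,
                      zone_nm: float = PROXIMAL_ZONE_NM) -> StereologyResult:
    """End-to-end report for one experiment's annotations."""
    from .density import tally_annotations

    tally = tally_annotations(annotations, experiment_id, zone_nm)
    fractions = point_compartment_fractions(annotations, grid, zone_nm)
    return rli_report(tally, fractions)
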