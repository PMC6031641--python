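import numpy as np
import pytest

from clemquant.annotations import (
    ImageFrame,
    MembraneContour,
    MicrographAnnotation,
    Particle,
)

# Summary rows of the published seven-experiment labeling table, used as
# inputs by the stereology tests: observed and expected counts per
# compartment (cytoplasm / uncoated membrane / coated membrane), the
# printed Yates chi-squared statistic and p-value.
LABELING_TABLE = {
    "Control1": {"n_images": 26, "obs": (26, 1, 0), "exp": (23.7, 1.1, 2.2),
                 "chi2": 0.716, "p": 0.398},
    "Control2": {"n_images": 29, "obs": (44, 0, 0), "exp": (37.9, 1.6, 4.5),
                 "chi2": 2.971, "p": 0.085},
    "Control3": {"n_images": 6, "obs": (18, 0, 0), "exp": (17.2, 0.3, 0.5),
                 "chi2": 0.438, "p": 0.508},
    "Rapamycin1": {"n_images": 26, "obs": (69, 7, 89), "exp": (123.3, 7.7, 34.0),
                   "chi2": 38.531, "p": 5.39e-10},
    "Rapamycin2": {"n_images": 16, "obs": (15, 15, 36), "exp": (50.9, 3.7, 11.5),
                   "chi2": 29.301, "p": 6.20e-8},
    "Rapamycin3": {"n_images": 5, "obs": (4, 1, 5), "exp": (7.1, 1.1, 1.8),
                   "chi2": 1.092, "p": 0.30},
    "Rapamycin4": {"n_images": 8, "obs": (7, 8, 31), "exp": (38.1, 0.6, 7.3),
                   "chi2": 33.196, "p": 8.33e-9},
}


@pytest.fixture
def frame():
    """1000 x 800 nm frame at 2 nm/px, 70 nm sections."""
    return ImageFrame(width_px=500, height_px=400, nm_per_px=2.0)


@pytest.fixture
def straight_membrane(frame):
    """Horizontal membrane at y = 300 nm; cytoplasm below (left side)."""
    contour = MembraneContour(
        [(0.0, 300.0), (1000.0, 300.0)],
        coat_intervals=[(400.0, 600.0)],
        side_convention="left",
    )
    return MicrographAnnotation(frame, [contour], [])


def random_polyline(rng, n_vertices=8, scale=500.0):
    """Random self-avoiding-ish polyline for oracle tests: a monotone-x walk."""
    xs = np.sort(rng.uniform(0, scale, n_vertices))
    ys = rng.uniform(0, scale, n_vertices)
    return np.column_stack([xs, ys])


def dense_sample_closest(vertices, point, n=10_000):
    """Brute-force closest approach by densely sampling the polyline."""
    v = np.asarray(vertices, float)
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.linspace(0.0, cum[-1], n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seglen) - 1)
    frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    pts = v[idx] + frac[:, None] * seg[idx]
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    i = int(np.argmin(d))
    return float(d[i]), float(s[i])


def make_annotation(vertices, particles=(), frame=None, **contour_kw):
    fr = frame or ImageFrame(width_px=1000, height_px=1000, nm_per_px=1.0)
    contour = MembraneContour(np.asarray(vertices, float), **contour_kw)
    parts = [Particle(tuple(p)) for p in particles]
    return MicrographAnnotation(fr, [contour], parts)
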