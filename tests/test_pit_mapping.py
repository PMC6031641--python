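"""Pit/distal classification, normalized arc positions, idealized projection."""

import numpy as np
import pytest

from clemquant.annotations import MembraneContour, point_at_arc
from clemquant.pit_mapping import (
    classify_and_normalize,
    combine,
    frequency_per_region,
    idealized_projection,
    proximity_comparison,
)

from conftest import dense_sample_closest


@pytest.fixture
def pit_contour():
    """Straight membrane with the middle 200 nm marked as the pit."""
    return MembraneContour([(0.0, 0.0), (1000.0, 0.0)],
                           pit_marks=(400.0, 600.0), side_convention="left")


class TestClassifyAndNormalize:
    def test_midpoint_is_half(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(500.0, 20.0)])
        row = pm.table.iloc[0]
        assert row["label"] == "pit"
        assert row["s"] == pytest.approx(0.5)
        assert row["proximity_nm"] == pytest.approx(20.0)

    def test_pit_edge_is_closed_interval(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(400.0, 10.0)])
        row = pm.table.iloc[0]
        assert row["label"] == "pit"
        assert row["s"] == pytest.approx(0.0)

    def test_distal_signed_offsets(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(300.0, 10.0), (650.0, 10.0)])
        offs = pm.table.sort_values("particle")["arc_offset_nm"].to_numpy()
        assert offs[0] == pytest.approx(-100.0)  # before pit start
        assert offs[1] == pytest.approx(50.0)    # after pit end

    def test_extracellular_excluded(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(500.0, -10.0)])
        assert len(pm.table) == 0
        assert pm.n_excluded == 1

    def test_missing_pit_marks(self):
        c = MembraneContour([(0.0, 0.0), (100.0, 0.0)])
        with pytest.raises(ValueError):
            classify_and_normalize(c, [(50.0, 5.0)])

    def test_against_dense_foot_sampling(self):
        """Curved contour: labels and s vs brute-force arc sampling."""
        rng = np.random.default_rng(17)
        t = np.linspace(0, np.pi, 60)
        v = np.column_stack([t * 150.0, 40.0 * np.sin(t * 2.0)])
        total = np.sum(np.hypot(*np.diff(v, axis=0).T))
        c = MembraneContour(v, pit_marks=(0.3 * total, 0.6 * total))
        pts = np.column_stack([rng.uniform(30, 420, 200),
                               rng.uniform(-80, 80, 200)])
        pm = classify_and_normalize(c, pts)
        p0, p1 = c.pit_marks
        for _, row in pm.table.iterrows():
            q = pts[int(row["particle"])]
            d_ref, s_ref = dense_sample_closest(v, q, n=50_000)
            if min(abs(s_ref - p0), abs(s_ref - p1)) < 0.5:
                continue  # pit-edge band
            expect = "pit" if p0 <= s_ref <= p1 else "distal"
            assert row["label"] == expect
            if expect == "pit":
                assert abs(row["s"] - (s_ref - p0) / (p1 - p0)) < 1e-3

    def test_rigid_motion_invariance(self, pit_contour):
        rng = np.random.default_rng(18)
        pts = np.column_stack([rng.uniform(100, 900, 40),
                               rng.uniform(2, 60, 40)])
        pm0 = classify_and_normalize(pit_contour, pts)
        ang = 73.0
        th = np.radians(ang)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c2 = pit_contour.transformed(ang, (123.0, -45.0))
        pts2 = pts @ R.T + np.array([123.0, -45.0])
        pm1 = classify_and_normalize(c2, pts2)
        assert (pm0.table["label"] == pm1.table["label"]).all()
        assert np.allclose(pm0.table["proximity_nm"], pm1.table["proximity_nm"],
                           atol=1e-9)
        pit0 = pm0.table["s"].dropna().to_numpy()
        pit1 = pm1.table["s"].dropna().to_numpy()
        assert np.allclose(pit0, pit1, atol=1e-9)


class TestIdealizedProjection:
    def test_two_points_per_particle(self, pit_contour):
        rng = np.random.default_rng(19)
        pts = np.column_stack([rng.uniform(50, 950, 25), rng.uniform(2, 40, 25)])
        pm = classify_and_normalize(pit_contour, pts)
        proj = idealized_projection(pm)
        assert len(proj) == 2 * len(pm.table)

    def test_apex_point(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(500.0, 1e-9)])
        proj = idealized_projection(pm, pit_diameter_nm=100.0)
        assert np.allclose(proj["x_nm"], 0.0, atol=1e-6)
        assert np.allclose(proj["y_nm"], -50.0, atol=1e-6)

    def test_proximity_beyond_apex_along_axis(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(500.0, 17.0)])
        proj = idealized_projection(pm, pit_diameter_nm=100.0)
        assert np.allclose(proj["y_nm"], -67.0)
        assert np.allclose(proj["x_nm"], 0.0, atol=1e-9)

    def test_proximity_preserved_exactly(self, pit_contour):
        rng = np.random.default_rng(20)
        pts = np.column_stack([rng.uniform(50, 950, 60), rng.uniform(1, 45, 60)])
        pm = classify_and_normalize(pit_contour, pts)
        proj = idealized_projection(pm)
        pit = proj[proj["label"] == "pit"]
        err = np.abs(np.hypot(pit["x_nm"], pit["y_nm"]) - 50.0) - pit["proximity_nm"]
        assert np.abs(err).max() < 1e-9 * 50.0
        distal = proj[proj["label"] == "distal"]
        assert np.allclose(np.abs(distal["y_nm"]), distal["proximity_nm"])

    def test_mirror_symmetry(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(450.0, 12.0), (700.0, 9.0)])
        proj = idealized_projection(pm)
        for pid in proj["particle"].unique():
            pair = proj[proj["particle"] == pid]
            assert pair["x_nm"].sum() == pytest.approx(0.0, abs=1e-9)
            assert pair["y_nm"].iloc[0] == pair["y_nm"].iloc[1]


class TestProximityComparison:
    def test_identical_groups_not_significant(self, pit_contour):
        pts = ([(430.0 + i, 10.0) for i in range(8)]
               + [(700.0 + i, 10.0 + (i % 2) * 0.5) for i in range(8)]
               + [(440.0 + i, 10.5) for i in range(0, 8, 2)])
        pm = classify_and_normalize(pit_contour, pts)
        res = proximity_comparison(pm)
        assert res["welch_p"] > 0.05

    def test_label_swap_negates_difference(self, pit_contour):
        rng = np.random.default_rng(21)
        pts = [(rng.uniform(410, 590), rng.uniform(15, 25)) for _ in range(12)]
        pts += [(rng.uniform(650, 950), rng.uniform(5, 12)) for _ in range(12)]
        pm = classify_and_normalize(pit_contour, pts)
        res = proximity_comparison(pm)
        swapped = pm.table.copy()
        swapped["label"] = swapped["label"].map({"pit": "distal", "distal": "pit"})
        pm.table = swapped
        res2 = proximity_comparison(pm)
        assert res2["difference"] == pytest.approx(-res["difference"])
        assert res2["welch_p"] == pytest.approx(res["welch_p"])

    def test_too_small_group(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(500.0, 10.0), (700.0, 10.0),
                                                  (750.0, 11.0)])
        with pytest.raises(ValueError):
            proximity_comparison(pm)


class TestFrequency:
    def test_empty(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [])
        df = frequency_per_region([pm])
        assert df["pit_count"].sum() == 0

    def test_count_conservation(self, pit_contour):
        rng = np.random.default_rng(22)
        maps = []
        n_rows = 0
        for img in range(4):
            pts = np.column_stack([rng.uniform(50, 950, 10),
                                   rng.uniform(2, 40, 10)])
            pm = classify_and_normalize(pit_contour, pts, image_index=img)
            n_rows += len(pm.table)
            maps.append(pm)
        df = frequency_per_region(maps)
        assert int(df["pit_count"].sum() + df["distal_count"].sum()) == n_rows

    def test_rate_normalization_recorded(self, pit_contour):
        pm = classify_and_normalize(pit_contour, [(500.0, 10.0)])
        df = frequency_per_region([pm])
        assert df["pit_per_nm"].iloc[0] == pytest.approx(1 / 200.0)


class TestEndToEndGroundTruth:
    def test_labels_match_generator_truth(self):
        """Pit/distal labels agree with anchored-particle ground truth."""
        from clemquant.resolution import TagGeometryModel
        from clemquant.synthetic import SceneConfig, generate_scene

        ext = TagGeometryModel(16.5, 19.5, 22.0, orientation_law="perpendicular")
        kink = TagGeometryModel(6.5, 9.5, 22.0, orientation_law="perpendicular")
        n_total, n_agree = 0, 0
        for seed in range(10):
            cfg = SceneConfig(n_pits=1, cytoplasm_density=0, membrane_density=0,
                              coat_density=0, tag_model=ext, distal_tag_model=kink,
                              anchored_rate_pit_per_nm=0.02,
                              anchored_rate_distal_per_nm=0.005, seed=seed)
            ann, truth = generate_scene(cfg)
            pm = classify_and_normalize(ann.contours[0], ann.particles)
            anchored = truth[truth["anchored"]]
            merged = pm.table.merge(anchored, on="particle")
            p0, p1 = ann.contours[0].pit_marks
            near_edge = np.minimum(np.abs(merged["anchor_s_nm"] - p0),
                                   np.abs(merged["anchor_s_nm"] - p1)) < 1.0
            ok = ((merged["label"] == "pit")
                  == (merged["conformation"] == "extended")) | near_edge
            n_total += len(merged)
            n_agree += int(ok.sum())
        assert n_total > 100
        assert n_agree / n_total >= 0.98
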