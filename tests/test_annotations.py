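"""Geometry kernel and coordinate-file I/O."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clemquant.annotations import (
    SIDE_CYTOPLASM,
    SIDE_EXTRACELLULAR,
    ImageFrame,
    MembraneContour,
    MicrographAnnotation,
    Particle,
    arc_length,
    closest_approach,
    point_at_arc,
)
from clemquant.pointfile import (
    PointFileError,
    read_metadata,
    read_point_file,
    write_metadata,
    write_point_file,
)

from conftest import dense_sample_closest, random_polyline


class TestArcLength:
    def test_square_path(self):
        c = MembraneContour([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert arc_length(c) == pytest.approx(30.0)

    def test_three_four_five(self):
        c = MembraneContour([(0, 0), (3, 4)])
        assert arc_length(c) == pytest.approx(5.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = random_polyline(rng, n_vertices=int(rng.integers(2, 12)))
            c = MembraneContour(v)
            brute = sum(
                float(np.hypot(*(v[i + 1] - v[i]))) for i in range(len(v) - 1)
            )
            assert arc_length(c) == pytest.approx(brute, rel=1e-12)

    def test_additive_over_vertices(self):
        rng = np.random.default_rng(1)
        v = random_polyline(rng, 9)
        c = MembraneContour(v)
        partials = [arc_length(c, k) for k in range(len(v))]
        diffs = np.diff(partials)
        seglens = np.hypot(*(np.diff(v, axis=0).T))
        assert np.allclose(diffs, seglens)
        assert partials[-1] == pytest.approx(arc_length(c))

    def test_position_out_of_range(self):
        c = MembraneContour([(0, 0), (10, 0)])
        with pytest.raises(ValueError):
            arc_length(c, 11.0)
        with pytest.raises(IndexError):
            arc_length(c, 5)


class TestClosestApproach:
    def test_point_on_vertex(self):
        c = MembraneContour([(0, 0), (10, 0), (20, 5)])
        prox, foot, side = closest_approach(c, (10, 0))
        assert prox == pytest.approx(0.0, abs=1e-12)
        assert foot == pytest.approx(10.0)
        assert side == 0  # on membrane

    def test_perpendicular_offset_and_side(self):
        # membrane along +x; left convention puts cytoplasm at +y (raster)
        c = MembraneContour([(0, 0), (100, 0)], side_convention="left")
        prox, foot, side = closest_approach(c, (40, 25))
        assert prox == pytest.approx(25.0)
        assert foot == pytest.approx(40.0)
        assert side == SIDE_CYTOPLASM
        _, _, side2 = closest_approach(c, (40, -25))
        assert side2 == SIDE_EXTRACELLULAR

    def test_against_dense_sampling(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            v = random_polyline(rng, 10)
            c = MembraneContour(v)
            q = rng.uniform(-50, 550, 2)
            prox, foot, _ = closest_approach(c, q)
            d_ref, s_ref = dense_sample_closest(v, q)
            tol = arc_length(c) / 10_000  # sampling resolution
            assert prox == pytest.approx(d_ref, abs=tol)
            assert abs(foot - s_ref) < 5 * tol or prox == pytest.approx(d_ref, abs=1e-9)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(ValueError):
            MembraneContour([(5, 5), (5, 5)])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(angle=st.floats(0, 360), tx=st.floats(-1e3, 1e3), ty=st.floats(-1e3, 1e3),
           seed=st.integers(0, 100))
    def test_rigid_motion_invariance(self, angle, tx, ty, seed):
        rng = np.random.default_rng(seed)
        v = random_polyline(rng, 7)
        q = rng.uniform(0, 500, 2)
        c = MembraneContour(v)
        prox0, foot0, side0 = closest_approach(c, q)
        th = np.radians(angle)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c2 = c.transformed(angle, (tx, ty))
        q2 = R @ q + np.array([tx, ty])
        prox1, foot1, side1 = closest_approach(c2, q2)
        assert prox1 == pytest.approx(prox0, rel=1e-9, abs=1e-9)
        assert foot1 == pytest.approx(foot0, rel=1e-9, abs=1e-6)
        assert side1 == side0


class TestPointAtArc:
    def test_round_trip_with_closest_approach(self):
        rng = np.random.default_rng(3)
        v = random_polyline(rng, 8)
        c = MembraneContour(v)
        s = rng.uniform(0, arc_length(c), 50)
        pts, _, _ = point_at_arc(c, s)
        for si, p in zip(s, pts):
            prox, foot, _ = closest_approach(c, p)
            assert prox == pytest.approx(0.0, abs=1e-9)
            assert foot == pytest.approx(si, abs=1e-6)

    def test_normal_points_to_cytoplasm(self):
        c = MembraneContour([(0, 0), (100, 0)], side_convention="left")
        _, _, normal = point_at_arc(c, 50.0)
        assert normal[0] == pytest.approx([0.0, 1.0])  # +y is cytoplasmic


class TestContourValidation:
    def test_coat_interval_bounds(self):
        with pytest.raises(ValueError):
            MembraneContour([(0, 0), (10, 0)], coat_intervals=[(5, 15)])

    def test_overlapping_coat_intervals(self):
        with pytest.raises(ValueError):
            MembraneContour([(0, 0), (100, 0)], coat_intervals=[(0, 50), (40, 80)])

    def test_pit_marks_ordered(self):
        with pytest.raises(ValueError):
            MembraneContour([(0, 0), (100, 0)], pit_marks=(60, 40))


class TestPointFile:
    def test_grouping_by_object_and_contour(self, frame):
        text = "\n".join([
            "1 1 0 0 0",
            "1 1 10 0 0",
            "1 1 10 10 0",
            "2 1 50 50 0",
        ])
        anns = read_point_file(text, frame)
        assert len(anns) == 1
        assert len(anns[0].contours) == 1
        assert anns[0].contours[0].vertices.shape == (3, 2)
        assert len(anns[0].particles) == 1
        # px -> nm conversion by the frame scale
        assert anns[0].particles[0].center == (100.0, 100.0)

    def test_empty_stream(self, frame):
        assert read_point_file("", frame) == []

    def test_z_splits_images(self, frame):
        text = "1 1 0 0 0\n1 1 10 0 0\n1 1 0 0 1\n1 1 10 5 1\n"
        anns = read_point_file(text, frame)
        assert [a.image_index for a in anns] == [0, 1]

    def test_malformed_line_names_line_number(self, frame):
        with pytest.raises(PointFileError, match="line 2"):
            read_point_file("1 1 0 0 0\n1 1 zero 0 0\n", frame)
        with pytest.raises(PointFileError, match="5"):
            read_point_file("1 1 0 0\n", frame)

    def test_unknown_object_id_lists_admissible(self, frame):
        with pytest.raises(PointFileError, match="admissible"):
            read_point_file("7 1 0 0 0\n", frame)

    def test_round_trip(self, frame):
        rng = np.random.default_rng(4)
        anns = []
        for z in range(3):
            v = random_polyline(rng, 6, scale=700.0)
            contour = MembraneContour(v)
            particles = [Particle(tuple(rng.uniform(0, 700, 2))) for _ in range(4)]
            anns.append(MicrographAnnotation(frame, [contour], particles,
                                             image_index=z))
        buf = io.StringIO()
        write_point_file(anns, buf)
        back = read_point_file(buf.getvalue(), frame)
        assert len(back) == 3
        for a, b in zip(anns, back):
            assert np.allclose(a.contours[0].vertices, b.contours[0].vertices,
                               atol=1e-5)
            assert np.allclose(a.particle_array(), b.particle_array(), atol=1e-5)

    def test_write_read_idempotent_on_text(self, frame):
        text = "1 1 1.5 2.5 0\n1 1 30 40 0\n2 1 100 200 0\n"
        anns = read_point_file(text, frame)
        buf1 = io.StringIO()
        write_point_file(anns, buf1)
        buf2 = io.StringIO()
        write_point_file(read_point_file(buf1.getvalue(), frame), buf2)
        assert buf1.getvalue() == buf2.getvalue()


class TestMetadata:
    def test_round_trip(self):
        meta = {"nm_per_px": 2.0, "width_px": 500, "height_px": 400,
                "section_thickness_nm": 70.0, "condition": "rapamycin",
                "experiment_id": "e1", "side_convention": "left",
                "coat_intervals_nm": {1: [(100.0, 200.0), (300.0, 350.0)]},
                "pit_marks_nm": {1: (120.0, 180.0)}}
        buf = io.StringIO()
        write_metadata(meta, buf)
        back = read_metadata(buf.getvalue())
        assert back["nm_per_px"] == 2.0
        assert back["coat_intervals_nm"][1] == [(100.0, 200.0), (300.0, 350.0)]
        assert back["pit_marks_nm"][1] == (120.0, 180.0)
        assert back["condition"] == "rapamycin"

    def test_image_scoped_marks_round_trip(self, frame):
        meta = {"nm_per_px": 2.0, "width_px": 500, "height_px": 400,
                "coat_intervals_nm": {}, "pit_marks_nm": {},
                "per_image": {0: {"coat_intervals_nm": {1: [(10.0, 20.0)]},
                                  "pit_marks_nm": {1: (12.0, 18.0)}},
                              1: {"coat_intervals_nm": {1: [(30.0, 40.0)]},
                                  "pit_marks_nm": {}}}}
        buf = io.StringIO()
        write_metadata(meta, buf)
        back = read_metadata(buf.getvalue())
        assert back["per_image"][0]["coat_intervals_nm"][1] == [(10.0, 20.0)]
        assert back["per_image"][1]["coat_intervals_nm"][1] == [(30.0, 40.0)]
        # per-image marks land on the right image's contour
        text = "1 1 0 0 0\n1 1 30 0 0\n1 1 0 0 1\n1 1 30 0 1\n"
        anns = read_point_file(text, frame, per_image=back["per_image"])
        assert anns[0].contours[0].coat_intervals == [(10.0, 20.0)]
        assert anns[0].contours[0].pit_marks == (12.0, 18.0)
        assert anns[1].contours[0].coat_intervals == [(30.0, 40.0)]


class TestFrameValidation:
    @pytest.mark.parametrize("kw", [
        {"width_px": 0, "height_px": 10, "nm_per_px": 1.0},
        {"width_px": 10, "height_px": 10, "nm_per_px": -1.0},
        {"width_px": 10, "height_px": 10, "nm_per_px": 1.0,
         "section_thickness_nm": 0.0},
    ])
    def test_invalid_frames_rejected(self, kw):
        with pytest.raises(ValueError):
            ImageFrame(**kw)

    def test_particle_outside_frame_rejected(self):
        fr = ImageFrame(100, 100, 1.0)
        contour = MembraneContour([(0, 50), (100, 50)])
        with pytest.raises(ValueError):
            MicrographAnnotation(fr, [contour], [Particle((150.0, 50.0))])
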