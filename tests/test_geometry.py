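"""Distances, angles and the d1–d12 / g1–g10 measurement catalogues."""

import math

import numpy as np
import pytest

from nasometry import sample_face, project
from nasometry.geometry import (
    DegenerateGeometryError,
    UnitsError,
    angle_at_vertex,
    angle_between_lines,
    compute_angles,
    compute_linear,
    euclidean_distance,
    nostril_axis,
    plane_coords,
)
from nasometry.landmarks import View


class TestEuclideanDistance:
    def test_pythagorean_triple(self):
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_identical_points(self):
        assert euclidean_distance((2.5, -1, 7), (2.5, -1, 7)) == 0.0

    def test_matches_componentwise_oracle(self, rng):
        for dim in (2, 3):
            a = rng.normal(size=(1000, dim))
            b = rng.normal(size=(1000, dim))
            for pa, pb in zip(a, b):
                oracle = math.sqrt(sum((y - x) ** 2 for x, y in zip(pa, pb)))
                assert abs(euclidean_distance(pa, pb) - oracle) < 1e-12

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 3))
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_mixed_units_rejected(self):
        with pytest.raises(UnitsError):
            euclidean_distance((0, 0), (1, 1), units=("px", "mm"))

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance((0, 0), (1, 1, 1))


class TestVertexAngle:
    def test_right_angle(self):
        assert angle_at_vertex((1, 0), (0, 0), (0, 1)) == pytest.approx(90.0)

    def test_collinear_through_vertex_is_straight(self):
        # a dorsum with the hump point exactly on the n–r line reads 180°,
        # the post-surgical ideal for the kyphion angle
        n, k, r = (0.0, 10.0), (1.0, 8.0), (2.0, 6.0)
        assert angle_at_vertex(n, k, r) == pytest.approx(180.0, abs=1e-9)

    def test_matches_law_of_cosines_oracle(self, rng):
        for _ in range(500):
            li, lj, lk = rng.normal(size=(3, 2))
            a = math.dist(lj, lk)
            b = math.dist(lj, li)
            c = math.dist(li, lk)
            cosg = (a * a + b * b - c * c) / (2 * a * b)
            oracle = math.degrees(math.acos(max(-1.0, min(1.0, cosg))))
            assert abs(angle_at_vertex(li, lj, lk) - oracle) < 1e-9

    def test_degenerate_vertex_raises(self):
        with pytest.raises(DegenerateGeometryError, match="first"):
            angle_at_vertex((0, 0), (0, 0), (1, 1))


class TestLineAngle:
    def test_parallel_lines(self):
        assert angle_between_lines((0, 0), (1, 1), (5, 5), (7, 7)) == pytest.approx(0.0)

    def test_perpendicular_lines(self):
        assert angle_between_lines((0, 0), (1, 0), (0, 0), (0, 3)) == pytest.approx(90.0)

    def test_matches_atan2_oracle(self, rng):
        for _ in range(500):
            p1, p2, q1, q2 = rng.normal(size=(4, 2))
            a1 = math.atan2(p2[1] - p1[1], p2[0] - p1[0])
            a2 = math.atan2(q2[1] - q1[1], q2[0] - q1[0])
            diff = math.degrees(abs(a1 - a2)) % 360
            directed = min(diff, 360 - diff)
            assert abs(angle_between_lines(p1, p2, q1, q2, fold="directed") - directed) < 1e-9
            assert abs(angle_between_lines(p1, p2, q1, q2, fold="acute") - min(directed, 180 - directed)) < 1e-9

    def test_degenerate_line_raises(self):
        with pytest.raises(DegenerateGeometryError):
            angle_between_lines((0, 0), (0, 0), (1, 1), (2, 2))


class TestNostrilAxis:
    BASE = {
        "sbal_l": (-9.0, 0.0),
        "sbal_r": (9.0, 0.0),
        "c'_l": (-4.0, 8.0),
        "c'_r": (4.0, 8.0),
        "cw_l": (-3.0, 2.0),
        "cw_r": (3.0, 2.0),
        "c_l": (-2.0, 9.0),
        "c_r": (2.0, 9.0),
    }

    def test_symmetric_base_axes_mirror(self):
        _, dl = nostril_axis("left", self.BASE)
        _, dr = nostril_axis("right", self.BASE)
        assert dl[0] == pytest.approx(-dr[0])
        assert dl[1] == pytest.approx(dr[1])

    def test_interaxial_equals_twice_axis_to_vertical(self):
        _, dr = nostril_axis("right", self.BASE)
        per_side = angle_between_lines((0, 0), dr, (0, 0), (0, 1), fold="acute")
        interaxial = angle_between_lines((0, 0), nostril_axis("left", self.BASE)[1], (0, 0), dr, fold="directed")
        assert interaxial == pytest.approx(2 * per_side, abs=1e-9)

    def test_horizontal_axis_makes_zero_with_horizontal(self):
        pts = {"sbal_r": (0.0, 0.0), "c'_r": (5.0, 0.0)}
        _, d = nostril_axis("right", pts)
        assert angle_between_lines((0, 0), d, (0, 0), (1, 0), fold="acute") == pytest.approx(0.0)

    def test_pca_axis_agrees_in_direction(self):
        _, d_simple = nostril_axis("right", self.BASE)
        _, d_pca = nostril_axis("right", self.BASE, method="pca")
        assert float(np.dot(d_simple, d_pca)) > 0.7

    def test_missing_landmark_named(self):
        with pytest.raises(KeyError, match="sbal_r"):
            nostril_axis("right", {"c'_r": (0, 1)})


class TestCatalogues:
    def test_twelve_linear_measurements(self, views):
        ms = compute_linear(views)
        assert [m.id for m in ms] == [f"d{i}" for i in range(1, 13)]
        assert all(not m.missing and m.value >= 0 for m in ms)

    def test_linear_values_match_pairwise_distance(self, views, face):
        for m in compute_linear(views):
            ann = views[m.plane.value]
            a, b = m.endpoints
            oracle = euclidean_distance(tuple(ann.points[a]), tuple(ann.points[b]))
            assert m.value == pytest.approx(oracle, rel=1e-12)

    def test_symmetric_face_nasal_width_is_twice_alare_offset(self):
        p = sample_face(21, asym_sd=0.0, overrides={"tilt_deg": 0.0})
        face = p.face3d()
        width = [m for m in compute_linear(face) if m.id == "d5"][0]
        assert width.value == pytest.approx(2 * abs(face.points["al_r"][0]), rel=1e-9)

    def test_missing_endpoint_flagged_not_dropped(self, views):
        reduced = dict(views)
        pruned = {pid: p for pid, p in views["frontal"].points.items() if pid != "mf_l"}
        reduced["frontal"] = type(views["frontal"])(view="frontal", points=pruned, image_size=views["frontal"].image_size)
        ms = compute_linear(reduced)
        d1 = [m for m in ms if m.id == "d1"][0]
        assert d1.missing and d1.value is None
        assert len(ms) == 12

    def test_angle_count_with_and_without_hump(self, views, hump_views):
        without = compute_angles(views, hump_present=False)
        with_hump = compute_angles(hump_views, hump_present=True)
        assert len(without) == 9 and "g7" not in {m.id for m in without}
        assert len(with_hump) == 10 and "g7" in {m.id for m in with_hump}

    def test_hump_requested_but_kyphion_absent_raises(self, views):
        with pytest.raises(KeyError, match="k"):
            compute_angles(views, hump_present=True)

    def test_vertex_angles_match_their_triples(self, hump_views):
        triples = {
            "g1": ("g", "n", "prn"),
            "g2": ("n", "prn", "pg"),
            "g3": ("g", "sn", "pg"),
            "g4": ("n", "prn", "sn"),
            "g5": ("c_r", "sn", "ls"),
            "g7": ("n", "k", "r"),
            "g8": ("al_l", "prn", "al_r"),
        }
        angles = {m.id: m for m in compute_angles(hump_views, hump_present=True)}
        for gid, (a, v, b) in triples.items():
            ann = hump_views[angles[gid].view.value]
            pts = {pid: (p.u, -p.v) for pid, p in ann.points.items()}
            oracle = angle_at_vertex(pts[a], pts[v], pts[b])
            assert angles[gid].value == pytest.approx(oracle, abs=1e-9)

    def test_angles_within_range(self, hump_views):
        for m in compute_angles(hump_views, hump_present=True):
            assert 0.0 <= m.value <= 180.0


class TestInvariances:
    def test_planar_rigid_motion_all_measurements(self, rng, hump_views):
        """Rotating + translating every view's pixel annotation leaves all 12
        distances and 10 angles unchanged to 1e-9 relative."""
        from nasometry.landmarks import Point2D, ViewAnnotation

        lin0 = np.array([m.value for m in compute_linear(hump_views)])
        angles0 = compute_angles(hump_views, hump_present=True)
        ang0 = np.array([m.value for m in angles0])
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        shift = rng.normal(size=2) * 40
        moved = {}
        for view, ann in hump_views.items():
            pts = {}
            for pid, p in ann.points.items():
                q = np.array([c * p.u - s * p.v, s * p.u + c * p.v]) + shift
                pts[pid] = Point2D(*q)
            moved[view] = ViewAnnotation(view=view, points=pts, image_size=(10_000, 10_000))
        lin1 = np.array([m.value for m in compute_linear(moved)])
        angles1 = compute_angles(moved, hump_present=True)
        ang1 = np.array([m.value for m in angles1])
        np.testing.assert_allclose(lin1, lin0, rtol=1e-9)
        # g10 is referenced to the image horizontal, so an in-plane rotation
        # shifts each side's angle by the rotation angle (folded to [0, 90]);
        # every other angle is a pure landmark relation and must not move
        np.testing.assert_allclose(ang1[:-1], ang0[:-1], rtol=1e-9, atol=1e-9)
        theta_deg = np.degrees(theta)
        d0, d1 = angles0[-1].detail, angles1[-1].detail
        for side in ("left_deg", "right_deg"):
            candidates = [abs(((d0[side] + sgn * theta_deg) + 90) % 180 - 90) for sgn in (+1, -1)]
            assert min(abs(cand - d1[side]) for cand in candidates) < 1e-6

    def test_uniform_scaling_scales_distances_not_angles(self, hump_views):
        from nasometry.landmarks import Point2D, ViewAnnotation

        factor = 2.75
        scaled = {
            view: ViewAnnotation(
                view=view,
                points={pid: Point2D(p.u * factor, p.v * factor) for pid, p in ann.points.items()},
                image_size=(5000, 5000),
            )
            for view, ann in hump_views.items()
        }
        lin0 = np.array([m.value for m in compute_linear(hump_views)])
        lin1 = np.array([m.value for m in compute_linear(scaled)])
        np.testing.assert_allclose(lin1, factor * lin0, rtol=1e-9)
        ang0 = np.array([m.value for m in compute_angles(hump_views, hump_present=True)])
        ang1 = np.array([m.value for m in compute_angles(scaled, hump_present=True)])
        np.testing.assert_allclose(ang1, ang0, rtol=1e-9, atol=1e-9)
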