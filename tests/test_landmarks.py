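"""Landmark vocabulary, per-view annotations and 3D aggregation."""

import numpy as np
import pytest

from nasometry import sample_face, project
from nasometry.landmarks import (
    AggregationError,
    AggregationPolicy,
    Laterality,
    Point2D,
    View,
    ViewAnnotation,
    aggregate_views,
    canonical_landmarks,
    expand_point_ids,
    landmark,
    read_annotations_csv,
    read_annotations_json,
    validate_annotation,
    visibility_set,
    write_annotations_csv,
    write_annotations_json,
)


class TestVocabulary:
    def test_twenty_three_definitions(self):
        defs = canonical_landmarks()
        assert len(defs) == 23
        assert len({d.symbol for d in defs}) == 23

    def test_expansion_yields_37_points(self):
        ids = expand_point_ids()
        assert len(ids) == 37
        n_mid = sum(1 for d in canonical_landmarks() if d.laterality is Laterality.MIDLINE)
        n_bil = sum(1 for d in canonical_landmarks() if d.laterality is Laterality.BILATERAL)
        assert (n_mid, n_bil) == (9, 14)
        assert n_mid + 2 * n_bil == 37

    @pytest.mark.parametrize(
        "symbol,name,laterality",
        [
            ("prn", "Pronasale", Laterality.MIDLINE),
            ("al", "Alare", Laterality.BILATERAL),
            ("k", "Kyphion", Laterality.MIDLINE),
            ("ch", "Cheilion", Laterality.BILATERAL),
        ],
    )
    def test_lookup(self, symbol, name, laterality):
        d = landmark(symbol)
        assert d.name == name
        assert d.laterality is laterality

    def test_unknown_symbol_raises(self):
        with pytest.raises(KeyError):
            landmark("xyz")

    def test_profile_only_points_hidden_frontally(self):
        frontal = visibility_set("frontal")
        assert "k" not in frontal and "r" not in frontal
        assert len(frontal) == 35
        lateral = visibility_set("lateral")
        assert {"k", "r", "prn"} <= lateral
        assert all(not pid.endswith("_l") for pid in lateral), "lateral shows the right side only"

    def test_every_point_visible_somewhere(self):
        covered = set()
        for view in View:
            covered |= visibility_set(view)
        assert covered == set(expand_point_ids())


class TestValidation:
    def _annotation(self, points, view="frontal", size=(100, 100)):
        return ViewAnnotation(view=view, points=points, image_size=size)

    def test_clean_annotation_passes(self):
        rep = validate_annotation(self._annotation({"prn": (50, 50), "al_l": (40, 55)}))
        assert rep.ok

    def test_out_of_bounds_point_reported(self):
        rep = validate_annotation(self._annotation({"prn": (-3, 10)}))
        assert rep.out_of_bounds == ["prn"]

    def test_unknown_id_reported(self):
        rep = validate_annotation(self._annotation({"nose_tip": (10, 10)}))
        assert rep.unknown_ids == ["nose_tip"]

    def test_profile_landmark_in_frontal_view_warns(self):
        rep = validate_annotation(self._annotation({"k": (50, 50)}))
        assert rep.visibility_warnings == ["k"]
        assert validate_annotation(self._annotation({"k": (50, 50)}, view="lateral")).ok


class TestAggregation:
    def _triple(self, seed=3, tilt=0.0, hump=True):
        p = sample_face(seed, overrides={"tilt_deg": tilt, "hump_present": hump})
        ann = {v: project(p, v) for v in ("frontal", "lateral", "mental")}
        return p, ann

    def test_round_trip_recovers_ground_truth(self):
        """Projecting a synthetic face to three views and aggregating must
        reproduce every observed coordinate to numerical precision."""
        p, ann = self._triple()
        alpha = p.alpha_eff
        face = aggregate_views(
            ann["frontal"], ann["lateral"], ann["mental"],
            scales={v: alpha for v in ("frontal", "lateral", "mental")}, units="mm",
        )
        g = p.coords["g"]
        for pid, c in face.points.items():
            truth = p.coords[pid] - g
            for ax in range(3):
                if np.isfinite(c[ax]) and "mirror" not in face.provenance[pid][ax]:
                    assert abs(c[ax] - truth[ax]) < 1e-9

    def test_aggregation_idempotent_on_consistent_triple(self):
        p, ann = self._triple(seed=5)
        a1 = aggregate_views(ann["frontal"], ann["lateral"], ann["mental"])
        a2 = aggregate_views(ann["frontal"], ann["lateral"], ann["mental"])
        for pid in a1.points:
            np.testing.assert_array_equal(a1.points[pid], a2.points[pid])

    def test_two_view_mean_of_equal_values_unchanged(self):
        # a point seen identically (after anchoring) in frontal and mental
        # keeps its x coordinate exactly
        p, ann = self._triple(seed=9)
        face = aggregate_views(ann["frontal"], ann["lateral"], ann["mental"])
        pid = "al_r"
        assert "+".join(["frontal", "mental"]) in face.provenance[pid][0]

    def test_frontal_only_point_has_missing_depth(self):
        p, ann = self._triple(seed=9)
        face = aggregate_views(ann["frontal"], ann["lateral"], ann["mental"])
        assert np.isnan(face.points["zy_l"][2])  # cheek point: no lateral/mental view
        assert face.provenance["zy_l"][2] == "missing"

    def test_mirror_policy_fills_far_side_depth(self):
        p, ann = self._triple(seed=9)
        face = aggregate_views(
            ann["frontal"], ann["lateral"], ann["mental"], policy=AggregationPolicy(mirror_missing_z=True)
        )
        assert np.isfinite(face.points["al_l"][2])
        assert "mirror" in face.provenance["al_l"][2]

    def test_missing_anchor_raises_naming_view(self):
        p, ann = self._triple(seed=9)
        broken = ViewAnnotation(
            view="lateral",
            points={pid: pt for pid, pt in ann["lateral"].points.items() if pid != "g"},
            image_size=ann["lateral"].image_size,
        )
        with pytest.raises(AggregationError, match="lateral.*'g'|'g'.*lateral"):
            aggregate_views(ann["frontal"], broken, ann["mental"])


class TestAnnotationIO:
    def test_json_round_trip(self, tmp_path, views):
        path = tmp_path / "ann.json"
        write_annotations_json(path, views)
        back = read_annotations_json(path)
        assert set(back) == set(views)
        for view, ann in views.items():
            for pid, p in ann.points.items():
                assert back[view].points[pid] == p

    def test_csv_round_trip_bit_stable(self, tmp_path, views):
        path = tmp_path / "ann.csv"
        write_annotations_csv(path, {"p0": views})
        back = read_annotations_csv(path)
        for view, ann in views.items():
            for pid, p in ann.points.items():
                q = back["p0"][view].points[pid]
                assert q.u == p.u and q.v == p.v  # repr round-trip is exact
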