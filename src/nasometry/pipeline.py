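"""Participant-level measurement pipeline: landmarks → report.

Given one participant's three annotated views (ground truth or CNN
predictions, in pixels) and the calibration parameters, this module computes
the full anthropometric report: the 12 linear measurements converted to
millimetres through the view-specific ratios and the head-tilt coefficient,
the 9/10 angles in degrees, the eight neoclassical canon verdicts, and the
nose-bridge classification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import CalibrationParams, scale_factor, tilt_coefficient, to_millimetres
from .canons import BridgeClassification, CanonResult, classify_bridge, evaluate_canons
from .geometry import (
    AngularMeasurement,
    DEFAULT_PLANES,
    LINEAR_CATALOGUE,
    LinearMeasurement,
    compute_angles,
    euclidean_distance,
)
from .landmarks import View, ViewAnnotation, read_annotations_json

__all__ = ["MeasurementReport", "measure_participant", "load_dataset_dir"]


@dataclass
class MeasurementReport:
    linear: list[LinearMeasurement]
    angular: list[AngularMeasurement]
    canons: list[CanonResult]
    bridge: BridgeClassification | None
    tilt_coefficient: float
    hump_present: bool

    def to_dict(self) -> dict:
        return {
            "linear_mm": {
                m.id: (None if m.value is None else round(m.value, 6)) for m in self.linear
            },
            "angles_deg": {
                m.id: (None if m.value is None else round(m.value, 6)) for m in self.angular
            },
            "canons": [dataclasses.asdict(c) for c in self.canons],
            "bridge": None if self.bridge is None else dataclasses.asdict(self.bridge),
            "tilt_coefficient": self.tilt_coefficient,
            "hump_present": self.hump_present,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def rows(self) -> list[dict]:
        """Flat rows (id, definition, view, value, units) for CSV export."""
        rows = [
            {
                "id": m.id,
                "definition": f"{m.endpoints[0]}-{m.endpoints[1]}",
                "view": m.plane.value,
                "value": m.value,
                "units": m.units,
            }
            for m in self.linear
        ]
        rows += [
            {"id": m.id, "definition": m.definition, "view": m.view.value, "value": m.value, "units": "deg"}
            for m in self.angular
        ]
        return rows


def _tilt_from_views(views: dict[str, ViewAnnotation], calib: CalibrationParams) -> float:
    mental = views.get("mental")
    lateral = views.get("lateral")
    if mental is None or lateral is None:
        return 1.0
    for ann in (mental, lateral):
        if "g" not in ann.points or "prn" not in ann.points:
            return 1.0
    d_m = euclidean_distance(tuple(mental.points["g"]), tuple(mental.points["prn"]))
    d_l = euclidean_distance(tuple(lateral.points["g"]), tuple(lateral.points["prn"]))
    if d_l == 0:
        return 1.0
    return tilt_coefficient(d_m, d_l, mode=calib.tilt_mode)


def measure_participant(
    views: dict[str, ViewAnnotation],
    calib: CalibrationParams | None = None,
    hump_present: bool | None = None,
    canon_tolerance: float = 0.05,
    straight_band_mm: float = 1.0,
    broken_threshold_mm: float = 5.0,
    planes: dict | None = None,
) -> MeasurementReport:
    """Compute the full anthropometric report for one participant.

    ``views`` maps view name → pixel annotation (at least the views the
    requested measurements need).  ``hump_present=None`` infers the hump from
    the presence of the kyphion (k) in the lateral annotation.
    """
    calib = calib or CalibrationParams()
    views = {View(k).value: v for k, v in views.items()}
    T = _tilt_from_views(views, calib)
    planes = {k: View(v) for k, v in (planes or DEFAULT_PLANES).items()}

    linear: list[LinearMeasurement] = []
    for mid, name, (a, b) in LINEAR_CATALOGUE:
        view = planes[mid]
        ann = views.get(view.value)
        if ann is None or a not in ann.points or b not in ann.points:
            linear.append(LinearMeasurement(mid, name, (a, b), view, None, "mm", missing=True))
            continue
        pa = np.array(ann.points[a])
        pb = np.array(ann.points[b])
        d_px = euclidean_distance(pa, pb)
        mid_uv = (pa + pb) / 2.0
        c = float(np.linalg.norm(mid_uv - np.asarray(calib.optical_center)))
        d_mm = to_millimetres(d_px, view, calib, T=T, c=c)
        linear.append(LinearMeasurement(mid, name, (a, b), view, d_mm, "mm"))

    lateral = views.get("lateral")
    if hump_present is None:
        hump_present = bool(lateral is not None and "k" in lateral.points)
    angular = compute_angles(views, hump_present=hump_present)

    canons: list[CanonResult] = []
    if "frontal" in views:
        canons = evaluate_canons(views["frontal"], tolerance=canon_tolerance)

    bridge = None
    if lateral is not None and all(p in lateral.points for p in ("n", "prn", "r")):
        d_lat = scale_factor(calib) * (calib.d_s / calib.d_f)
        pts = {p: (lateral.points[p].u, -lateral.points[p].v) for p in ("n", "prn", "r")}
        bridge = classify_bridge(
            pts["n"],
            pts["prn"],
            pts["r"],
            D=d_lat,
            straight_band_mm=straight_band_mm,
            broken_threshold_mm=broken_threshold_mm,
        )

    return MeasurementReport(
        linear=linear,
        angular=angular,
        canons=canons,
        bridge=bridge,
        tilt_coefficient=T,
        hump_present=hump_present,
    )


def load_dataset_dir(root) -> list[dict]:
    """Read a generated dataset directory back into records.

    Expects ``participant_*/annotations.json`` and the per-view PNGs the
    generator wrote; images are returned as uint8 arrays (missing images are
    tolerated — annotation-only workflows need none).
    """
    from PIL import Image

    root = Path(root)
    records = []
    for pdir in sorted(root.glob("participant_*")):
        ann_path = pdir / "annotations.json"
        if not ann_path.exists():
            continue
        rec: dict = {"id": pdir.name, "annotations": read_annotations_json(ann_path), "images": {}}
        for view in ("frontal", "lateral", "mental"):
            img_path = pdir / f"{view}.png"
            if img_path.exists():
                rec["images"][view] = np.asarray(Image.open(img_path))
        records.append(rec)
    if not records:
        raise FileNotFoundError(f"no participant_*/annotations.json under {root}")
    return records
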