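"""Canonical landmark vocabulary, per-view annotations, and 3D aggregation.

The measurement protocol uses 23 named soft-tissue landmarks (9 midline +
14 bilateral), which expand to 37 concrete points per face.  Each face is
photographed in three standardized views:

* ``frontal`` — image plane carries (x, y): subject-left→right and
  inferior→superior;
* ``lateral`` — right profile; image plane carries (z, y): posterior→anterior
  depth and height;
* ``mental`` — basal view of the nasal base from below the chin; image plane
  carries (x, w), where w is the coordinate along the glabella→pronasale axis
  within the midsagittal plane (the direction a basal photograph is shot
  perpendicular to).

3D coordinates live in a face-mounted frame with its origin at the glabella:
x to the subject's right, y superior, z anterior.  Missing coordinates are
represented explicitly with NaN, never with a silent zero.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "View",
    "Laterality",
    "LandmarkDefinition",
    "Point2D",
    "ViewAnnotation",
    "Face3D",
    "AggregationPolicy",
    "AggregationError",
    "canonical_landmarks",
    "expand_point_ids",
    "visibility_set",
    "validate_annotation",
    "aggregate_views",
    "read_annotations_json",
    "write_annotations_json",
    "read_annotations_csv",
    "write_annotations_csv",
    "EXTRA_LANDMARKS",
    "MISSING",
]


class View(str, Enum):
    FRONTAL = "frontal"
    LATERAL = "lateral"
    MENTAL = "mental"


class Laterality(str, Enum):
    MIDLINE = "midline"
    BILATERAL = "bilateral"


@dataclass(frozen=True)
class LandmarkDefinition:
    symbol: str
    name: str
    laterality: Laterality
    visible_in: frozenset[View]

    def point_ids(self) -> tuple[str, ...]:
        """Concrete point identifiers this definition expands to."""
        if self.laterality is Laterality.MIDLINE:
            return (self.symbol,)
        return (f"{self.symbol}_l", f"{self.symbol}_r")


class Point2D(NamedTuple):
    u: float  # horizontal pixel coordinate (left → right in the image)
    v: float  # vertical pixel coordinate (top → bottom in the image)


# Default per-view visibility.  The protocol never photographs kyphion (k) and
# rhinion (r) frontally — they are profile-only dorsum points.  The lateral
# (right-profile) view shows the midline profile chain plus the near-side
# (right) periocular/alar points; the mental view shows the nasal base.
_MIDLINE = [
    ("tr", "Trichion"),
    ("g", "Glabella"),
    ("n", "Nasion"),
    ("prn", "Pronasale"),
    ("k", "Kyphion"),
    ("r", "Rhinion"),
    ("sn", "Subnasale"),
    ("ls", "Labiale superius"),
    ("pg", "Pogonion"),
]
_BILATERAL = [
    ("en", "Endocanthion"),
    ("ex", "Exocanthion"),
    ("al", "Alare"),
    ("al'", "Alare'"),
    ("ac", "Alar curvature"),
    ("zy", "Zygion"),
    ("mf", "Maxillofrontale"),
    ("sbal", "Subalare"),
    ("c", "Columellar peak"),
    ("cw", "Columellar waist"),
    ("lc", "Lateral crus"),
    ("la", "Lateral alar"),
    ("c'", "Soft triangle"),
    ("ch", "Cheilion"),
]

_LATERAL_MIDLINE = {"tr", "g", "n", "k", "r", "prn", "sn", "ls", "pg"}
_LATERAL_NEARSIDE = {"en", "ex", "al", "al'", "ac", "sbal", "c", "c'", "cw", "la"}
_MENTAL_MIDLINE = {"g", "prn", "sn"}
_MENTAL_BILATERAL = {"al", "al'", "ac", "c'", "cw", "sbal", "c", "lc", "la"}


def _default_visibility(symbol: str, laterality: Laterality) -> frozenset[View]:
    views: set[View] = set()
    if symbol not in {"k", "r"}:
        views.add(View.FRONTAL)
    if symbol in _LATERAL_MIDLINE or symbol in _LATERAL_NEARSIDE:
        views.add(View.LATERAL)
    if symbol in _MENTAL_MIDLINE or symbol in _MENTAL_BILATERAL:
        views.add(View.MENTAL)
    return frozenset(views)


def _build_canonical() -> tuple[LandmarkDefinition, ...]:
    defs = []
    for symbol, name in _MIDLINE:
        defs.append(
            LandmarkDefinition(symbol, name, Laterality.MIDLINE, _default_visibility(symbol, Laterality.MIDLINE))
        )
    for symbol, name in _BILATERAL:
        defs.append(
            LandmarkDefinition(symbol, name, Laterality.BILATERAL, _default_visibility(symbol, Laterality.BILATERAL))
        )
    return tuple(defs)


_CANONICAL: tuple[LandmarkDefinition, ...] = _build_canonical()
_BY_SYMBOL = {d.symbol: d for d in _CANONICAL}

#: Optional extra annotation points used only by the neoclassical canons that
#: reference structures outside the 23-landmark model: gnathion (gn, chin
#: base), supra-aurale/sub-aurale (sa/sba, ear length) and the pupil centre.
EXTRA_LANDMARKS: tuple[LandmarkDefinition, ...] = (
    LandmarkDefinition("gn", "Gnathion", Laterality.MIDLINE, frozenset({View.FRONTAL, View.LATERAL})),
    LandmarkDefinition("sa", "Supra-aurale", Laterality.BILATERAL, frozenset({View.FRONTAL})),
    LandmarkDefinition("sba", "Sub-aurale", Laterality.BILATERAL, frozenset({View.FRONTAL})),
    LandmarkDefinition("pupil", "Pupil centre", Laterality.BILATERAL, frozenset({View.FRONTAL})),
)
_EXTRA_IDS = frozenset(pid for d in EXTRA_LANDMARKS for pid in d.point_ids())


def canonical_landmarks() -> list[LandmarkDefinition]:
    """The 23 canonical landmark definitions, in stable (midline-first) order."""
    return list(_CANONICAL)


def landmark(symbol: str) -> LandmarkDefinition:
    """Look up one canonical definition by its symbol (e.g. ``"prn"``)."""
    try:
        return _BY_SYMBOL[symbol]
    except KeyError:
        raise KeyError(f"unknown landmark symbol {symbol!r}") from None


def expand_point_ids(include_extras: bool = False) -> list[str]:
    """All concrete point identifiers (37 for the canonical set)."""
    ids = [pid for d in _CANONICAL for pid in d.point_ids()]
    if include_extras:
        ids += [pid for d in EXTRA_LANDMARKS for pid in d.point_ids()]
    return ids


def visibility_set(view: View | str, include_extras: bool = False) -> frozenset[str]:
    """Point ids visible in *view* under the default visibility convention.

    The lateral view is a right profile: only the ``_r`` instance of a
    bilateral landmark is visible there.
    """
    view = View(view)
    ids: set[str] = set()
    pool: Iterable[LandmarkDefinition] = (
        list(_CANONICAL) + list(EXTRA_LANDMARKS) if include_extras else _CANONICAL
    )
    for d in pool:
        if view not in d.visible_in:
            continue
        if d.laterality is Laterality.MIDLINE:
            ids.add(d.symbol)
        elif view is View.LATERAL:
            ids.add(f"{d.symbol}_r")
        else:
            ids.update(d.point_ids())
    return frozenset(ids)


def base_symbol(point_id: str) -> str:
    """Strip the ``_l``/``_r`` suffix from a concrete point id."""
    if point_id.endswith("_l") or point_id.endswith("_r"):
        return point_id[:-2]
    return point_id


def mirror_id(point_id: str) -> str:
    if point_id.endswith("_l"):
        return point_id[:-2] + "_r"
    if point_id.endswith("_r"):
        return point_id[:-2] + "_l"
    return point_id


@dataclass
class ViewAnnotation:
    """Landmark coordinates (pixels, image frame) for one photograph."""

    view: View
    points: dict[str, Point2D]
    image_size: tuple[int, int]  # (width, height) in px

    def __post_init__(self) -> None:
        self.view = View(self.view)
        self.points = {pid: Point2D(*p) for pid, p in self.points.items()}

    def array(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([[self.points[i].u, self.points[i].v] for i in ids], dtype=float)


@dataclass
class ValidationReport:
    unknown_ids: list[str] = field(default_factory=list)
    out_of_bounds: list[str] = field(default_factory=list)
    visibility_warnings: list[str] = field(default_factory=list)
    non_finite: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.unknown_ids or self.out_of_bounds or self.visibility_warnings or self.non_finite)


def validate_annotation(a: ViewAnnotation, include_extras: bool = True) -> ValidationReport:
    """Check an annotation against the vocabulary, image bounds and visibility."""
    report = ValidationReport()
    known = set(expand_point_ids(include_extras=True))
    visible = visibility_set(a.view, include_extras=True)
    w, h = a.image_size
    for pid, p in a.points.items():
        if pid not in known:
            report.unknown_ids.append(pid)
            continue
        if not (np.isfinite(p.u) and np.isfinite(p.v)):
            report.non_finite.append(pid)
            continue
        if not (0 <= p.u < w and 0 <= p.v < h):
            report.out_of_bounds.append(pid)
        if pid not in visible:
            report.visibility_warnings.append(pid)
    return report


MISSING = float("nan")


@dataclass
class Face3D:
    """Aggregated 3D landmark coordinates in the glabella-mounted frame.

    Coordinates are stored as length-3 arrays; a missing coordinate is NaN
    (the explicit sentinel — downstream code must check, never assume zero).
    ``provenance`` records, per point and axis, which view(s) the value came
    from (or ``"missing"`` / ``"midline-assumption"``).
    """

    points: dict[str, np.ndarray]
    units: str = "px"  # "px" or "mm"
    provenance: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def coord(self, pid: str) -> np.ndarray:
        return self.points[pid]

    def has_full(self, pid: str) -> bool:
        return pid in self.points and bool(np.all(np.isfinite(self.points[pid])))


class AggregationError(ValueError):
    pass


@dataclass
class AggregationPolicy:
    """How per-view observations combine into one Face3D.

    ``conflict``: "mean" averages an axis observed in two views;
    "frontal_priority" keeps the frontal observation.
    ``mirror_missing_z``: fill the depth of a far-side (left) bilateral point
    from its right-side mirror (exact for a symmetric face, an approximation
    otherwise).  ``assume_midline_x``: profile-only midline points (k, r) get
    x = 0.
    """

    conflict: str = "mean"
    mirror_missing_z: bool = False
    assume_midline_x: bool = True
    anchor: str = "g"


def _rel(a: ViewAnnotation, pid: str, anchor: str) -> tuple[float, float]:
    p = a.points[pid]
    g = a.points[anchor]
    return p.u - g.u, p.v - g.v


def aggregate_views(
    frontal: ViewAnnotation | None,
    lateral: ViewAnnotation | None,
    mental: ViewAnnotation | None,
    policy: AggregationPolicy | None = None,
    scales: Mapping[str, float] | None = None,
    units: str = "px",
) -> Face3D:
    """Fuse per-view 2D annotations into 3D coordinates L(x, y, z).

    Each view is translated so the anchor landmark (glabella) sits at the
    origin; view axes map into the face frame as documented in the module
    docstring.  ``scales`` gives a per-view multiplicative factor applied to
    pixel offsets (e.g. mm-per-px conversion ratios); default 1.

    The mental view contributes the x axis only: its in-plane vertical axis is
    the skewed g→prn coordinate, which cannot be resolved into z without the
    head-tilt geometry.  Depth for points unseen laterally is NaN unless
    ``policy.mirror_missing_z`` fills it from the mirror point.
    """
    policy = policy or AggregationPolicy()
    scales = dict(scales or {})
    views = {View.FRONTAL: frontal, View.LATERAL: lateral, View.MENTAL: mental}
    for view, ann in views.items():
        if ann is None:
            continue
        if policy.anchor not in ann.points:
            raise AggregationError(
                f"anchor landmark {policy.anchor!r} missing from the {view.value} view"
            )

    # per-axis observations: pid -> axis -> list[(source, value)]
    obs: dict[str, dict[int, list[tuple[str, float]]]] = {}

    def add(pid: str, axis: int, source: str, value: float) -> None:
        obs.setdefault(pid, {0: [], 1: [], 2: []})[axis].append((source, value))

    if frontal is not None:
        s = scales.get("frontal", 1.0)
        for pid in frontal.points:
            du, dv = _rel(frontal, pid, policy.anchor)
            add(pid, 0, "frontal", du * s)
            add(pid, 1, "frontal", -dv * s)
    if lateral is not None:
        s = scales.get("lateral", 1.0)
        for pid in lateral.points:
            du, dv = _rel(lateral, pid, policy.anchor)
            add(pid, 2, "lateral", du * s)
            add(pid, 1, "lateral", -dv * s)
    if mental is not None:
        s = scales.get("mental", 1.0)
        for pid in mental.points:
            du, dv = _rel(mental, pid, policy.anchor)
            add(pid, 0, "mental", du * s)

    points: dict[str, np.ndarray] = {}
    provenance: dict[str, tuple[str, str, str]] = {}
    for pid, axes in obs.items():
        coord = np.full(3, np.nan)
        prov = ["missing", "missing", "missing"]
        for axis, entries in axes.items():
            if not entries:
                continue
            if len(entries) == 1 or policy.conflict == "mean":
                coord[axis] = float(np.mean([v for _, v in entries]))
                prov[axis] = "+".join(src for src, _ in entries)
            elif policy.conflict == "frontal_priority":
                chosen = next((e for e in entries if e[0] == "frontal"), entries[0])
                coord[axis] = chosen[1]
                prov[axis] = chosen[0]
            else:
                raise AggregationError(f"unknown conflict policy {policy.conflict!r}")
        if np.isnan(coord[0]) and policy.assume_midline_x and base_symbol(pid) == pid:
            coord[0] = 0.0
            prov[0] = "midline-assumption"
        points[pid] = coord
        provenance[pid] = tuple(prov)  # type: ignore[assignment]

    if policy.mirror_missing_z:
        for pid in list(points):
            if np.isnan(points[pid][2]):
                twin = mirror_id(pid)
                if twin != pid and twin in points and np.isfinite(points[twin][2]):
                    points[pid][2] = points[twin][2]
                    prov = list(provenance[pid])
                    prov[2] = f"mirror({twin})"
                    provenance[pid] = tuple(prov)  # type: ignore[assignment]

    return Face3D(points=points, units=units, provenance=provenance)


# ---------------------------------------------------------------------------
# Annotation file I/O


def write_annotations_json(path, annotations: Mapping[str, ViewAnnotation]) -> None:
    """Write ``{view: {"image_size": [w, h], "points": {id: [u, v]}}}``."""
    payload = {
        View(view).value: {
            "image_size": list(ann.image_size),
            "points": {pid: [p.u, p.v] for pid, p in sorted(ann.points.items())},
        }
        for view, ann in annotations.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_annotations_json(path) -> dict[str, ViewAnnotation]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for view, block in payload.items():
        out[view] = ViewAnnotation(
            view=View(view),
            points={pid: Point2D(*uv) for pid, uv in block["points"].items()},
            image_size=tuple(block["image_size"]),
        )
    return out


def write_annotations_csv(path, participants: Mapping[str, Mapping[str, ViewAnnotation]]) -> None:
    """Long-form CSV: participant, view, point_id, u_px, v_px, width, height."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant", "view", "point_id", "u_px", "v_px", "width", "height"])
        for part in sorted(participants):
            for view in ("frontal", "lateral", "mental"):
                ann = participants[part].get(view)
                if ann is None:
                    continue
                w, h = ann.image_size
                for pid in sorted(ann.points):
                    p = ann.points[pid]
                    writer.writerow([part, view, pid, repr(float(p.u)), repr(float(p.v)), w, h])


def read_annotations_csv(path) -> dict[str, dict[str, ViewAnnotation]]:
    out: dict[str, dict[str, ViewAnnotation]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            part = out.setdefault(row["participant"], {})
            size = (int(row["width"]), int(row["height"]))
            ann = part.get(row["view"])
            if ann is None:
                ann = ViewAnnotation(view=View(row["view"]), points={}, image_size=size)
                part[row["view"]] = ann
            ann.points[row["point_id"]] = Point2D(float(row["u_px"]), float(row["v_px"]))
    return out
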