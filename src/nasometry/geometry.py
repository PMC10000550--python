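"""Planar distances, angles and the nasal measurement catalogues.

Twelve linear measurements (d1–d12) and ten angles (g1–g10) are defined on
landmark pairs/triples.  Every quantity is planar: it is measured inside one
view's image plane (frontal, lateral or mental), mirroring a protocol in
which callipers are replaced by pixel arithmetic on standardized photographs.

Distances are Euclidean; vertex angles are the arccos of the normalized dot
product of the two rays leaving the vertex; line-pair angles (nasofacial g6,
nostril-axis g10) compare direction vectors.  Angles are unit-free, so they
can be computed in raw pixels; distances carry a units flag so that the
calibration layer can convert px → mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landmarks import Face3D, View, ViewAnnotation

__all__ = [
    "DegenerateGeometryError",
    "UnitsError",
    "euclidean_distance",
    "angle_at_vertex",
    "angle_between_lines",
    "nostril_axis",
    "LinearMeasurement",
    "AngularMeasurement",
    "LINEAR_CATALOGUE",
    "ANGULAR_CATALOGUE",
    "DEFAULT_PLANES",
    "compute_linear",
    "compute_angles",
    "plane_coords",
]


class DegenerateGeometryError(ValueError):
    """A construction collapsed (coincident points, zero-length line)."""


class UnitsError(ValueError):
    """Operands carry incompatible units."""


def _vector_angle_deg(u: np.ndarray, w: np.ndarray) -> float:
    """Angle between two vectors via atan2 — accurate near 0° and 180°,
    where the arccos-of-dot-product form loses ~1e-6 degrees."""
    if u.shape == (2,):
        cross = abs(u[0] * w[1] - u[1] * w[0])
    else:
        cross = float(np.linalg.norm(np.cross(u, w)))
    return math.degrees(math.atan2(cross, float(np.dot(u, w))))


def euclidean_distance(a, b, units: tuple[str, str] | None = None) -> float:
    """Euclidean distance between two points of equal dimensionality.

    ``units``, if given, is the (unit_a, unit_b) pair; a mismatch raises
    :class:`UnitsError` rather than returning a meaningless number.
    """
    if units is not None and units[0] != units[1]:
        raise UnitsError(f"cannot mix units {units[0]!r} and {units[1]!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimensionality mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((b - a) ** 2)))


def angle_at_vertex(li, lj, lk) -> float:
    """Angle (degrees, [0, 180]) at vertex ``lj`` between rays to li and lk."""
    li = np.asarray(li, dtype=float)
    lj = np.asarray(lj, dtype=float)
    lk = np.asarray(lk, dtype=float)
    u = li - lj
    w = lk - lj
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        which = []
        if nu == 0.0:
            which.append("first")
        if nw == 0.0:
            which.append("third")
        raise DegenerateGeometryError(
            f"vertex angle undefined: {' and '.join(which)} point coincides with the vertex"
        )
    return _vector_angle_deg(u, w)


def angle_between_lines(p1, p2, q1, q2, fold: str = "acute") -> float:
    """Angle between lines p1–p2 and q1–q2, in degrees.

    ``fold="acute"`` returns the angle between the undirected lines, in
    [0, 90] (used for the nostril-axis-to-horizontal angle g10);
    ``fold="directed"`` returns the angle between the direction vectors
    p1→p2 and q1→q2, in [0, 180] (used for the nasofacial angle g6, where
    the orientation of the facial and nasal lines matters).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    u = p2 - p1
    w = q2 - q1
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu == 0.0 or nw == 0.0:
        raise DegenerateGeometryError("line with coincident endpoints")
    ang = _vector_angle_deg(u, w)
    if fold == "acute":
        return min(ang, 180.0 - ang)
    if fold == "directed":
        return ang
    raise ValueError(f"unknown fold convention {fold!r}")


def nostril_axis(
    side: str,
    mental_points: Mapping[str, Sequence[float]] | ViewAnnotation,
    method: str = "sbal-c'",
) -> tuple[np.ndarray, np.ndarray]:
    """Directed nostril axis for one side in the mental plane.

    Default definition: the line from the subalare (sbal, nostril floor)
    through the soft triangle (c', nostril apex) of that side.  The
    ``method="pca"`` alternative fits the principal axis of the four basal
    landmarks {sbal, c', cw, c}, oriented to agree with sbal→c'.

    Returns ``(origin, direction)``; direction is unit length.
    """
    if side not in {"left", "right"}:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    suffix = "_l" if side == "left" else "_r"
    if isinstance(mental_points, ViewAnnotation):
        pts = {pid: np.array([p.u, -p.v], dtype=float) for pid, p in mental_points.points.items()}
    else:
        pts = {pid: np.asarray(p, dtype=float) for pid, p in mental_points.items()}

    def need(pid: str) -> np.ndarray:
        if pid not in pts:
            raise KeyError(f"nostril axis needs landmark {pid!r} (missing)")
        return pts[pid]

    origin = need("sbal" + suffix)
    tip = need("c'" + suffix)
    d = tip - origin
    n = np.linalg.norm(d)
    if n == 0.0:
        raise DegenerateGeometryError(f"sbal{suffix} and c'{suffix} coincide")
    d = d / n
    if method == "sbal-c'":
        return origin, d
    if method == "pca":
        cloud = np.array([need(s + suffix) for s in ("sbal", "c'", "cw", "c")])
        centred = cloud - cloud.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
        if np.dot(axis, d) < 0:
            axis = -axis
        return cloud.mean(axis=0), axis
    raise ValueError(f"unknown nostril-axis method {method!r}")


# ---------------------------------------------------------------------------
# Measurement catalogues


@dataclass
class LinearMeasurement:
    id: str
    name: str
    endpoints: tuple[str, str]
    plane: View
    value: float | None
    units: str = "px"
    missing: bool = False


@dataclass
class AngularMeasurement:
    id: str
    name: str
    definition: str
    view: View
    value: float | None
    missing: bool = False
    detail: dict = field(default_factory=dict)


#: d1..d12: (name, endpoints).  Side-specific measurements use the right side
#: by default (the side the lateral view shows).
LINEAR_CATALOGUE: list[tuple[str, str, tuple[str, str]]] = [
    ("d1", "Nasal root", ("mf_l", "mf_r")),
    ("d2", "Nasal height", ("n", "sn")),
    ("d3", "Nasal length", ("n", "prn")),
    ("d4", "Nasal tip protrusion", ("sn", "prn")),
    ("d5", "Nasal width", ("al_l", "al_r")),
    ("d6", "Anatomical width", ("ac_l", "ac_r")),
    ("d7", "Inter canthal width", ("en_l", "en_r")),
    ("d8", "Ala length", ("ac_r", "prn")),
    ("d9", "Nostril floor width", ("sbal_r", "sn")),
    ("d10", "Columella width", ("c'_l", "c'_r")),
    ("d11", "Superior width of the columella", ("cw_l", "cw_r")),
    ("d12", "Ala thickness", ("al'_r", "c'_r")),
]

#: Source view per linear measurement: widths frontal, profile lengths
#: lateral, nasal-base widths mental.  Overridable.
DEFAULT_PLANES: dict[str, View] = {
    "d1": View.FRONTAL,
    "d5": View.FRONTAL,
    "d6": View.FRONTAL,
    "d7": View.FRONTAL,
    "d2": View.LATERAL,
    "d3": View.LATERAL,
    "d4": View.LATERAL,
    "d8": View.LATERAL,
    "d9": View.MENTAL,
    "d10": View.MENTAL,
    "d11": View.MENTAL,
    "d12": View.MENTAL,
}

ANGULAR_CATALOGUE: list[tuple[str, str, str, View]] = [
    ("g1", "Nasofrontal", "g-n-prn", View.LATERAL),
    ("g2", "Nasomental", "n-prn-pg", View.LATERAL),
    ("g3", "Facial convexity", "g-sn-pg", View.LATERAL),
    ("g4", "Nasal tip", "n-prn-sn", View.LATERAL),
    ("g5", "Nasolabial", "c-sn-ls", View.LATERAL),
    ("g6", "Nasofacial", "lines n-prn / g-pg", View.LATERAL),
    ("g7", "Kyphion", "n-k-r", View.LATERAL),
    ("g8", "Alar slope", "al-prn-al", View.MENTAL),
    ("g9", "Interaxial", "nostril axis / nostril axis", View.MENTAL),
    ("g10", "Nostril axis", "nostril axis / horizontal", View.MENTAL),
]

_VERTEX_TRIPLES = {
    "g1": ("g", "n", "prn"),
    "g2": ("n", "prn", "pg"),
    "g3": ("g", "sn", "pg"),
    "g4": ("n", "prn", "sn"),
    "g5": ("c_r", "sn", "ls"),
    "g7": ("n", "k", "r"),
    "g8": ("al_l", "prn", "al_r"),
}


def plane_coords(face: Face3D, view: View) -> dict[str, np.ndarray]:
    """Project Face3D coordinates into one view's measurement plane.

    frontal → (x, y); lateral → (z, y); mental → (x, w) with w the coordinate
    along the g→prn axis within the midsagittal plane (the basal camera's
    in-image vertical).  Points lacking a needed coordinate are dropped.
    """
    view = View(view)
    out: dict[str, np.ndarray] = {}
    if view is View.FRONTAL:
        for pid, c in face.points.items():
            if np.isfinite(c[0]) and np.isfinite(c[1]):
                out[pid] = np.array([c[0], c[1]])
        return out
    if view is View.LATERAL:
        for pid, c in face.points.items():
            if np.isfinite(c[2]) and np.isfinite(c[1]):
                out[pid] = np.array([c[2], c[1]])
        return out
    # mental
    if not (face.has_full("g") and face.has_full("prn")):
        raise DegenerateGeometryError("mental plane needs g and prn with full 3D coordinates")
    g = face.points["g"]
    prn = face.points["prn"]
    e = np.array([prn[1] - g[1], prn[2] - g[2]])  # (y, z) direction of g→prn
    n = np.linalg.norm(e)
    if n == 0.0:
        raise DegenerateGeometryError("g and prn coincide in the midsagittal plane")
    e = e / n
    for pid, c in face.points.items():
        if np.all(np.isfinite(c)):
            w = (c[1] - g[1]) * e[0] + (c[2] - g[2]) * e[1]
            out[pid] = np.array([c[0], w])
    return out


def _source_points(
    source: Face3D | Mapping[str, ViewAnnotation], view: View
) -> dict[str, np.ndarray]:
    if isinstance(source, Face3D):
        return plane_coords(source, view)
    ann = source.get(view.value) or source.get(view)  # type: ignore[call-overload]
    if ann is None:
        return {}
    # flip v so the in-plane frame is right-handed with "up" positive
    return {pid: np.array([p.u, -p.v]) for pid, p in ann.points.items()}


def compute_linear(
    source: Face3D | Mapping[str, ViewAnnotation],
    planes: Mapping[str, View] | None = None,
) -> list[LinearMeasurement]:
    """The 12 linear measurements, each taken in its source view plane.

    ``source`` is either an aggregated :class:`Face3D` (values in its units)
    or a mapping view-name → :class:`ViewAnnotation` (values in px).  A
    measurement whose endpoints are unavailable is returned flagged missing,
    never silently dropped.
    """
    planes = {k: View(v) for k, v in (planes or DEFAULT_PLANES).items()}
    units = source.units if isinstance(source, Face3D) else "px"
    cache = {view: _source_points(source, view) for view in View}
    out = []
    for mid, name, (a, b) in LINEAR_CATALOGUE:
        view = planes[mid]
        pts = cache[view]
        if a in pts and b in pts:
            out.append(LinearMeasurement(mid, name, (a, b), view, euclidean_distance(pts[a], pts[b]), units))
        else:
            out.append(LinearMeasurement(mid, name, (a, b), view, None, units, missing=True))
    return out


def compute_angles(
    source: Face3D | Mapping[str, ViewAnnotation],
    hump_present: bool,
    nostril_method: str = "sbal-c'",
) -> list[AngularMeasurement]:
    """The angular catalogue: g1–g7 in the lateral plane, g8–g10 mental.

    Returns 10 angles when ``hump_present`` (the kyphion angle g7 = n-k-r is
    defined), 9 otherwise.  g9 is the angle between the two directed nostril
    axes; g10 is the acute angle of each nostril axis to the image horizontal,
    reported as the left/right mean with per-side values in ``detail``.
    """
    lateral = _source_points(source, View.LATERAL)
    mental = _source_points(source, View.MENTAL)
    if hump_present and "k" not in lateral:
        raise KeyError("hump_present=True but kyphion landmark 'k' is unavailable")
    out: list[AngularMeasurement] = []
    for gid, name, definition, view in ANGULAR_CATALOGUE:
        if gid == "g7" and not hump_present:
            continue
        pts = lateral if view is View.LATERAL else mental
        value: float | None = None
        missing = False
        detail: dict = {}
        try:
            if gid in _VERTEX_TRIPLES:
                a, v, b = _VERTEX_TRIPLES[gid]
                value = angle_at_vertex(pts[a], pts[v], pts[b])
            elif gid == "g6":
                value = angle_between_lines(pts["n"], pts["prn"], pts["g"], pts["pg"], fold="directed")
            elif gid == "g9":
                _, dl = nostril_axis("left", pts, method=nostril_method)
                _, dr = nostril_axis("right", pts, method=nostril_method)
                value = angle_between_lines((0, 0), dl, (0, 0), dr, fold="directed")
            elif gid == "g10":
                horiz = np.array([1.0, 0.0])
                per_side = {}
                for side in ("left", "right"):
                    _, d = nostril_axis(side, pts, method=nostril_method)
                    per_side[side] = angle_between_lines((0, 0), d, (0, 0), horiz, fold="acute")
                detail = {f"{s}_deg": v for s, v in per_side.items()}
                value = float(np.mean(list(per_side.values())))
        except KeyError:
            missing = True
        out.append(AngularMeasurement(gid, name, definition, view, value, missing=missing, detail=detail))
    return out
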