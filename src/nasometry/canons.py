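"""Neoclassical facial proportions and nose-bridge profile classification.

Eight neoclassical canons relate frontal facial distances, e.g. the
naso-oral canon ch–ch = 1.5 (al–al).  A canon is *satisfied* when
|lhs − target·rhs| ≤ τ·target·rhs for a relative tolerance τ (default 5%;
the raw observed ratio is always reported so users can apply their own
criterion).  Canons 5–8 reference points outside the core 23-landmark model
(gnathion, ear landmarks sa/sba, pupil centre); when those are absent the
canon is reported not-evaluable rather than erroring.

The nasal bridge is classified from the lateral profile by the signed
perpendicular deviation (mm) of the rhinion r — the bone–cartilage junction —
from the n–prn line (positive = anterior of the line):

    straight  |delta| ≤ 1.0
    convex    delta > 1.0
    concave   −5.0 ≤ delta < −1.0
    broken    delta < −5.0

Boundary ties resolve to the milder class (exactly 1.0 → straight, exactly
−5.0 → concave); both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .geometry import euclidean_distance
from .landmarks import Face3D, View, ViewAnnotation

__all__ = [
    "CanonResult",
    "BridgeClassification",
    "CANON_DEFINITIONS",
    "evaluate_canons",
    "classify_bridge",
    "classify_bridge_delta",
    "bridge_delta",
]

# float guard so that exactly constructed ratios register as satisfied at
# tolerance 0 despite binary rounding of targets like 0.43
_ABS_GUARD = 1e-9


@dataclass
class CanonResult:
    canon_id: int
    name: str
    definition: str
    lhs: float | None
    rhs: float | None
    target_ratio: float
    observed_ratio: float | None
    satisfied: bool | None
    evaluable: bool
    tolerance: float


#: canon_id -> (name, definition string, target ratio, lhs spec, rhs spec).
#: lhs/rhs specs are either a point pair ("a", "b"), a tuple of pairs to be
#: averaged over sides, or "HORIZ:a:b" for a horizontal (|Δx|) distance.
CANON_DEFINITIONS: list[tuple[int, str, str, float, object, object]] = [
    (1, "Orbitonasal", "en-en = al-al", 1.0, ("en_l", "en_r"), ("al_l", "al_r")),
    (2, "Orbital", "en-en = ex-en", 1.0, ("en_l", "en_r"), (("ex_l", "en_l"), ("ex_r", "en_r"))),
    (3, "Naso-oral", "ch-ch = 1.5 (al-al)", 1.5, ("ch_l", "ch_r"), ("al_l", "al_r")),
    (4, "Nasofacial", "al-al = 0.25 (zy-zy)", 0.25, ("al_l", "al_r"), ("zy_l", "zy_r")),
    (5, "Three-section facial profile", "n-sn = 1/3 (tr-gn)", 1.0 / 3.0, ("n", "sn"), ("tr", "gn")),
    (6, "Nose height equals ear length", "n-sn = sa-sba", 1.0, ("n", "sn"), (("sa_l", "sba_l"), ("sa_r", "sba_r"))),
    (7, "Nose height to face height", "n-sn = 0.43 (n-gn)", 0.43, ("n", "sn"), ("n", "gn")),
    (
        8,
        "Mouth corner to alare vs pupil",
        "ch-en = ch-pupil (horizontally)",
        1.0,
        ("HORIZ", ("ch_l", "en_l"), ("ch_r", "en_r")),
        ("HORIZ", ("ch_l", "pupil_l"), ("ch_r", "pupil_r")),
    ),
]


def _frontal_points(source) -> dict[str, np.ndarray]:
    if isinstance(source, Face3D):
        out = {}
        for pid, c in source.points.items():
            if np.isfinite(c[0]) and np.isfinite(c[1]):
                out[pid] = np.array([c[0], c[1]])
        return out
    if isinstance(source, ViewAnnotation):
        if View(source.view) is not View.FRONTAL:
            raise ValueError("canons are evaluated on the frontal view")
        return {pid: np.array([p.u, -p.v]) for pid, p in source.points.items()}
    return {pid: np.asarray(p, dtype=float) for pid, p in source.items()}


def _measure(spec, pts: Mapping[str, np.ndarray]) -> float | None:
    if isinstance(spec, tuple) and spec and spec[0] == "HORIZ":
        vals = []
        for a, b in spec[1:]:
            if a not in pts or b not in pts:
                return None
            vals.append(abs(pts[a][0] - pts[b][0]))
        return float(np.mean(vals))
    if isinstance(spec[0], tuple):  # average over side pairs
        vals = []
        for a, b in spec:
            if a not in pts or b not in pts:
                return None
            vals.append(euclidean_distance(pts[a], pts[b]))
        return float(np.mean(vals))
    a, b = spec
    if a not in pts or b not in pts:
        return None
    return euclidean_distance(pts[a], pts[b])


def evaluate_canons(
    source: Face3D | ViewAnnotation | Mapping[str, Sequence[float]],
    tolerance: float = 0.05,
) -> list[CanonResult]:
    """Evaluate the eight neoclassical canons on frontal-plane coordinates.

    ``source`` may be an aggregated Face3D (its (x, y) coordinates are used),
    a frontal ViewAnnotation, or a plain mapping point-id → (x, y).  Canon
    satisfaction is scale-invariant, so pixel coordinates are fine.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pts = _frontal_points(source)
    results = []
    for cid, name, definition, target, lhs_spec, rhs_spec in CANON_DEFINITIONS:
        lhs = _measure(lhs_spec, pts)
        rhs = _measure(rhs_spec, pts)
        if lhs is None or rhs is None or rhs == 0.0:
            results.append(CanonResult(cid, name, definition, lhs, rhs, target, None, None, False, tolerance))
            continue
        ratio = lhs / rhs
        goal = target * rhs
        ok = abs(lhs - goal) <= tolerance * goal + _ABS_GUARD * max(1.0, goal)
        results.append(CanonResult(cid, name, definition, lhs, rhs, target, ratio, bool(ok), True, tolerance))
    return results


# ---------------------------------------------------------------------------
# Bridge classification


@dataclass
class BridgeClassification:
    delta_mm: float
    bridge_class: str
    straight_band_mm: float = 1.0
    broken_threshold_mm: float = 5.0


def classify_bridge_delta(
    delta_mm: float,
    straight_band_mm: float = 1.0,
    broken_threshold_mm: float = 5.0,
) -> str:
    """Map a signed bridge deviation (mm, anterior positive) to its class."""
    if not np.isfinite(delta_mm):
        raise ValueError(f"bridge deviation must be finite, got {delta_mm}")
    if abs(delta_mm) <= straight_band_mm:
        return "straight"
    if delta_mm > straight_band_mm:
        return "convex"
    if delta_mm >= -broken_threshold_mm:
        return "concave"
    return "broken"


def bridge_delta(n, prn, r, D: float = 1.0) -> float:
    """Signed perpendicular deviation (mm) of r from the n–prn line.

    Points are 2D lateral-plane coordinates (a, b) = (anterior, superior) —
    i.e. image (u, −v) for a right-facing profile — in pixels; ``D`` is the
    px→mm scale for the lateral view.  Positive deviation means r lies
    anterior of (above) the n–prn line.
    """
    n = np.asarray(n, dtype=float)
    prn = np.asarray(prn, dtype=float)
    r = np.asarray(r, dtype=float)
    t = prn - n
    norm = np.linalg.norm(t)
    if norm == 0.0:
        from .geometry import DegenerateGeometryError

        raise DegenerateGeometryError("n and prn coincide: bridge line undefined")
    # unit normal of the bridge line with a positive anterior (+a) component
    nhat = np.array([-t[1], t[0]]) / norm
    if nhat[0] < 0:
        nhat = -nhat
    return float(np.dot(r - n, nhat)) * D


def classify_bridge(
    n,
    prn,
    r,
    D: float = 1.0,
    profile: Sequence[Sequence[float]] | None = None,
    straight_band_mm: float = 1.0,
    broken_threshold_mm: float = 5.0,
) -> BridgeClassification:
    """Classify the nasal bridge from lateral-plane landmarks.

    If a dense dorsal ``profile`` polyline is supplied, the deviation is
    evaluated at the profile point nearest to the annotated r (a guard
    against a slightly displaced rhinion annotation); otherwise at r itself.
    """
    r = np.asarray(r, dtype=float)
    if profile is not None and len(profile) > 0:
        prof = np.asarray(profile, dtype=float)
        r = prof[np.argmin(np.sum((prof - r) ** 2, axis=1))]
    delta = bridge_delta(n, prn, r, D)
    cls = classify_bridge_delta(delta, straight_band_mm, broken_threshold_mm)
    return BridgeClassification(delta, cls, straight_band_mm, broken_threshold_mm)
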