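"""Parametric synthetic faces with exact three-view ground truth.

The study protocol's own photographs are not redistributable, so this module
generates the stand-in: a parametric 3D face template (millimetres, glabella
origin) jittered per participant, orthographically projected into the three
standardized views, and rendered as a schematic face on a green background.

Orthographic projection matches the fixed-distance capture rig (approximately
telecentric); the mental (basal) camera is aimed perpendicular to the
glabella→pronasale line, and a head-tilt angle rotates the subject about the
x axis away from that pose, foreshortening the mental image by cos(tilt).

Ground truth is exact by construction: the emitted per-view annotations are
the projected landmark coordinates themselves, so measuring them with the
geometry module and converting px → mm recovers the generating face to
numerical precision (rasterization plays no role in the ground truth).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .landmarks import (
    Face3D,
    Point2D,
    View,
    ViewAnnotation,
    visibility_set,
    write_annotations_json,
)

__all__ = [
    "FaceParams",
    "TEMPLATE_MM",
    "sample_face",
    "project",
    "render",
    "generate_participants",
    "generate_dataset",
    "stratified_bridge_deltas",
]

# 3D template coordinates in mm: x subject-right, y superior, z anterior,
# glabella at the origin.  Right-side instance given; left is the x-mirror.
_TEMPLATE_MIDLINE: dict[str, tuple[float, float, float]] = {
    "tr": (0.0, 62.0, -8.0),
    "g": (0.0, 0.0, 0.0),
    "n": (0.0, -10.0, -6.0),
    "prn": (0.0, -44.0, 20.0),
    "sn": (0.0, -54.0, 9.0),
    "ls": (0.0, -66.0, 7.0),
    "pg": (0.0, -100.0, 2.0),
    "gn": (0.0, -112.0, -4.0),  # optional extra (canons 5, 7)
}
_TEMPLATE_RIGHT: dict[str, tuple[float, float, float]] = {
    "en": (17.0, -12.0, -4.0),
    "ex": (44.0, -13.0, -9.0),
    "mf": (10.0, -8.0, -5.0),
    "al": (17.0, -47.0, 6.0),
    "al'": (14.0, -49.0, 12.0),
    "ac": (19.0, -49.0, 2.0),
    "sbal": (9.0, -52.0, 8.0),
    "c": (3.0, -49.0, 15.0),
    "cw": (3.5, -51.5, 12.0),
    "c'": (5.5, -50.0, 13.5),
    "lc": (12.0, -43.0, 13.0),
    "la": (16.0, -44.0, 9.0),
    "zy": (67.0, -32.0, -22.0),
    "ch": (26.0, -72.0, 3.0),
    "sa": (72.0, -14.0, -38.0),  # optional extras (canons 6, 8)
    "sba": (72.0, -64.0, -38.0),
    "pupil": (30.0, -12.0, -6.0),
}
#: landmarks whose shape responds to the nasal width/height/protrusion scalars
_NASAL_SET = {"al", "al'", "ac", "sbal", "c", "cw", "c'", "lc", "la", "prn", "sn"}

_R_FRACTION = 0.45  # rhinion position along the n→prn chord
_K_FRACTION = 0.30  # kyphion position along the n→prn chord


def _build_template() -> dict[str, np.ndarray]:
    coords: dict[str, np.ndarray] = {}
    for pid, c in _TEMPLATE_MIDLINE.items():
        coords[pid] = np.array(c, dtype=float)
    for sym, c in _TEMPLATE_RIGHT.items():
        right = np.array(c, dtype=float)
        coords[f"{sym}_r"] = right
        coords[f"{sym}_l"] = right * np.array([-1.0, 1.0, 1.0])
    return coords


TEMPLATE_MM: dict[str, np.ndarray] = _build_template()


class FaceParamsError(ValueError):
    pass


@dataclass
class FaceParams:
    """One synthetic participant: 3D landmark coordinates plus render controls.

    ``bridge_delta`` is the signed deviation (mm, anterior positive) of the
    rhinion from the n–prn line and drives the generated profile exactly;
    ``alpha`` is the render scale in mm per pixel (None → auto so a face
    fills a 416 px frame proportionally at any image size).
    """

    coords: dict[str, np.ndarray]
    bridge_delta: float = 0.0
    hump_present: bool = False
    nasal_width: float = 1.0
    nasal_height: float = 1.0
    nasal_protrusion: float = 1.0
    alpha: float | None = None
    image_size: int = 416
    background: tuple[int, int, int] = (0, 177, 64)
    noise_sd: float = 2.0
    tilt_deg: float = 0.0
    seed: int = 0

    @property
    def alpha_eff(self) -> float:
        return self.alpha if self.alpha is not None else 0.5 * 416.0 / self.image_size

    def face3d(self) -> Face3D:
        return Face3D(points={pid: c.copy() for pid, c in self.coords.items()}, units="mm")


def _bridge_normal(n: np.ndarray, prn: np.ndarray) -> np.ndarray:
    """Unit normal to the n→prn chord within the midsagittal plane, anterior."""
    t = prn - n
    nrm = np.array([0.0, t[2], -t[1]])
    nrm /= np.linalg.norm(nrm)
    if nrm[2] < 0:
        nrm = -nrm
    return nrm


_OVERRIDE_FIELDS = {
    "bridge_delta",
    "hump_present",
    "nasal_width",
    "nasal_height",
    "nasal_protrusion",
    "alpha",
    "image_size",
    "background",
    "noise_sd",
    "tilt_deg",
}


def sample_face(
    seed: int,
    overrides: dict | None = None,
    jitter_sd: float = 1.5,
    asym_sd: float = 0.4,
) -> FaceParams:
    """Draw one participant: template + symmetric shape jitter + nose controls.

    Reproducible under ``seed``.  ``overrides`` pins any FaceParams field
    (e.g. ``{"bridge_delta": -3.0}``); out-of-range overrides raise
    :class:`FaceParamsError`.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_FIELDS
    if unknown:
        raise FaceParamsError(f"unknown override(s): {sorted(unknown)}")
    rng = np.random.default_rng(seed)

    coords: dict[str, np.ndarray] = {}
    for pid in _TEMPLATE_MIDLINE:
        jit = rng.normal(0.0, jitter_sd, size=2)  # midline points stay on x = 0
        coords[pid] = TEMPLATE_MM[pid] + np.array([0.0, jit[0], jit[1]])
    for sym in _TEMPLATE_RIGHT:
        jit = rng.normal(0.0, jitter_sd, size=3)  # shared (mirrored) component
        asym_r = rng.normal(0.0, asym_sd, size=3)
        asym_l = rng.normal(0.0, asym_sd, size=3)
        right = TEMPLATE_MM[f"{sym}_r"] + jit + asym_r
        left = (TEMPLATE_MM[f"{sym}_r"] + jit) * np.array([-1.0, 1.0, 1.0]) + asym_l
        coords[f"{sym}_r"] = right
        coords[f"{sym}_l"] = left

    # nose morphology controls
    width = float(overrides.get("nasal_width", rng.normal(1.0, 0.05)))
    height = float(overrides.get("nasal_height", rng.normal(1.0, 0.05)))
    protr = float(overrides.get("nasal_protrusion", rng.normal(1.0, 0.07)))
    for scale, name in ((width, "nasal_width"), (height, "nasal_height"), (protr, "nasal_protrusion")):
        if not 0.6 <= scale <= 1.6:
            raise FaceParamsError(f"{name}={scale} outside the plausible range [0.6, 1.6]")
    n_anchor = coords["n"].copy()
    for sym in _NASAL_SET:
        for pid in ([sym] if sym in _TEMPLATE_MIDLINE else [f"{sym}_l", f"{sym}_r"]):
            c = coords[pid]
            c[0] = c[0] * width
            c[1] = n_anchor[1] + (c[1] - n_anchor[1]) * height
            c[2] = n_anchor[2] + (c[2] - n_anchor[2]) * protr

    # bridge profile: rhinion (and kyphion, when humped) sit on / off the
    # n–prn chord by exactly bridge_delta
    hump_override = overrides.get("hump_present")
    if "bridge_delta" in overrides:
        delta = float(overrides["bridge_delta"])
    elif hump_override:
        delta = float(rng.uniform(1.5, 4.5))
    else:
        delta = float(np.clip(rng.normal(0.0, 2.0), -7.5, 5.5))
    if not -12.0 <= delta <= 8.0:
        raise FaceParamsError(f"bridge_delta={delta} outside the valid range [-12, 8] mm")
    hump = bool(hump_override) if hump_override is not None else delta > 1.0
    if hump and delta <= 1.0:
        raise FaceParamsError(
            f"hump_present=True requires a convex bridge (bridge_delta > 1 mm), got {delta}"
        )
    nrm = _bridge_normal(coords["n"], coords["prn"])
    chord = coords["prn"] - coords["n"]
    coords["r"] = coords["n"] + _R_FRACTION * chord + delta * nrm
    if hump:
        coords["k"] = coords["n"] + _K_FRACTION * chord + (delta + 0.8) * nrm

    params = FaceParams(
        coords=coords,
        bridge_delta=delta,
        hump_present=hump,
        nasal_width=width,
        nasal_height=height,
        nasal_protrusion=protr,
        alpha=overrides.get("alpha"),
        image_size=int(overrides.get("image_size", 416)),
        background=tuple(overrides.get("background", (0, 177, 64))),
        noise_sd=float(overrides.get("noise_sd", 2.0)),
        tilt_deg=float(overrides.get("tilt_deg", 0.0)),
        seed=seed,
    )
    _validate(params)
    return params


def _validate(p: FaceParams) -> None:
    if p.alpha is not None and p.alpha <= 0:
        raise FaceParamsError(f"alpha must be > 0, got {p.alpha}")
    if p.noise_sd < 0:
        raise FaceParamsError(f"noise_sd must be >= 0, got {p.noise_sd}")
    if p.image_size < 64:
        raise FaceParamsError(f"image_size must be >= 64, got {p.image_size}")
    if not -45.0 <= p.tilt_deg <= 45.0:
        raise FaceParamsError(f"tilt_deg must be within ±45°, got {p.tilt_deg}")
    alal = float(np.linalg.norm(p.coords["al_l"] - p.coords["al_r"]))
    if not 22.0 <= alal <= 48.0:
        raise FaceParamsError(f"al–al = {alal:.1f} mm outside the plausible range")


def _mental_axis(p: FaceParams, tilted: bool = True) -> np.ndarray:
    """In-image vertical direction of the mental view, in the (y, z) plane."""
    g = p.coords["g"]
    prn = p.coords["prn"]
    e = np.array([prn[1] - g[1], prn[2] - g[2]])
    e /= np.linalg.norm(e)
    phi = math.radians(p.tilt_deg) if tilted else 0.0
    c, s = math.cos(phi), math.sin(phi)
    return np.array([c * e[0] - s * e[1], s * e[0] + c * e[1]])


def _plane_ab(p: FaceParams, view: View) -> dict[str, np.ndarray]:
    """(a, b) mm coordinates in the view's image plane (a right, b up)."""
    view = View(view)
    out: dict[str, np.ndarray] = {}
    if view is View.MENTAL:
        axis = _mental_axis(p)
        g = p.coords["g"]
    for pid in visibility_set(view, include_extras=True):
        if pid not in p.coords:
            continue
        c = p.coords[pid]
        if view is View.FRONTAL:
            out[pid] = np.array([c[0], c[1]])
        elif view is View.LATERAL:
            out[pid] = np.array([c[2], c[1]])
        else:
            w = (c[1] - g[1]) * axis[0] + (c[2] - g[2]) * axis[1]
            out[pid] = np.array([c[0], w])
    return out


def project(params: FaceParams, view: View | str) -> ViewAnnotation:
    """Exact ground-truth landmark pixels for one view.

    Orthographic projection onto the view plane at 1/alpha px per mm, with
    the projected landmark cloud centred in the frame; only view-visible
    landmarks are emitted (kyphion only exists on humped faces).
    """
    view = View(view)
    ab = _plane_ab(params, view)
    arr = np.array(list(ab.values()))
    mid = (arr.min(axis=0) + arr.max(axis=0)) / 2.0
    half = params.image_size / 2.0
    inv_alpha = 1.0 / params.alpha_eff
    points = {
        pid: Point2D(half + (c[0] - mid[0]) * inv_alpha, half - (c[1] - mid[1]) * inv_alpha)
        for pid, c in ab.items()
    }
    return ViewAnnotation(view=view, points=points, image_size=(params.image_size, params.image_size))


# ---------------------------------------------------------------------------
# Rendering

_SKIN = (228, 198, 176)
_STROKE = (70, 45, 35)


def _chains(view: View, pts: dict[str, Point2D], hump: bool) -> list[list[str]]:
    if view is View.FRONTAL:
        chains = [
            ["en_l", "ex_l"],
            ["en_r", "ex_r"],
            ["mf_l", "n", "mf_r"],
            ["ac_l", "al_l", "sbal_l", "sn", "sbal_r", "al_r", "ac_r"],
            ["al'_l", "c'_l", "sn", "c'_r", "al'_r"],
            ["ch_l", "ls", "ch_r"],
            ["tr", "g", "n", "prn", "sn"],
        ]
    elif view is View.LATERAL:
        profile = ["tr", "g", "n"] + (["k"] if hump else []) + ["r", "prn", "sn", "ls", "pg", "gn"]
        chains = [
            profile,
            ["en_r", "ex_r"],
            ["ac_r", "al_r", "la_r", "c'_r", "sbal_r"],
            ["prn", "c_r", "cw_r", "sn"],
        ]
    else:
        chains = [
            ["ac_l", "al_l", "la_l", "lc_l", "prn", "lc_r", "la_r", "al_r", "ac_r"],
            ["sn", "sbal_l", "c'_l", "c_l", "prn"],
            ["sn", "sbal_r", "c'_r", "c_r", "prn"],
            ["sn", "cw_l", "cw_r", "sn"],
            ["g", "prn"],
        ]
    return [[pid for pid in chain if pid in pts] for chain in chains]


def _hull(points: np.ndarray) -> np.ndarray:
    """Andrew's monotone-chain convex hull (avoids a scipy dependency)."""
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]

    def half(iterable):
        out: list[np.ndarray] = []
        for p in iterable:
            while len(out) >= 2:
                a = out[-1] - out[-2]
                b = p - out[-2]
                if a[0] * b[1] - a[1] * b[0] > 0:
                    break
                out.pop()
            out.append(p)
        return out

    lower = half(pts)
    upper = half(pts[::-1])
    return np.array(lower[:-1] + upper[:-1])


def render(params: FaceParams, view: View | str, rng: np.random.Generator | None = None) -> np.ndarray:
    """Schematic face image (H×W×3 uint8) for one view.

    A skin-coloured region (dilated convex hull of the projected landmarks)
    on the configured green background, with dark feature polylines drawn
    through the landmark positions and a dot at every landmark, plus optional
    Gaussian pixel noise.  The drawn curves interpolate the ground-truth
    landmarks exactly, so a landmark regressor has image evidence to learn.
    """
    view = View(view)
    ann = project(params, view)
    size = params.image_size
    img = Image.new("RGB", (size, size), tuple(params.background))
    draw = ImageDraw.Draw(img)

    arr = np.array([[p.u, p.v] for p in ann.points.values()])
    hull = _hull(arr)
    centroid = hull.mean(axis=0)
    offset = hull - centroid
    norms = np.maximum(np.linalg.norm(offset, axis=1, keepdims=True), 1e-9)
    outer = centroid + offset + offset / norms * (0.06 * size)  # grown skin region
    draw.polygon([tuple(p) for p in outer], fill=_SKIN, outline=_STROKE)

    w = max(1, size // 200)
    for chain in _chains(view, ann.points, params.hump_present):
        if len(chain) >= 2:
            draw.line([ann.points[pid] for pid in chain], fill=_STROKE, width=w + 1, joint="curve")
    rdot = max(1.0, size / 250.0)
    for pid, p in ann.points.items():
        draw.ellipse([p.u - rdot, p.v - rdot, p.u + rdot, p.v + rdot], fill=(30, 20, 15))
    if view is View.FRONTAL:
        for side in ("_l", "_r"):
            if f"pupil{side}" in ann.points:
                p = ann.points[f"pupil{side}"]
                r = max(2.0, size / 120.0)
                draw.ellipse([p.u - r, p.v - r, p.u + r, p.v + r], outline=_STROKE, width=w)

    out = np.asarray(img, dtype=np.float64)
    if params.noise_sd > 0:
        if rng is None:
            view_offset = {"frontal": 0, "lateral": 1, "mental": 2}[view.value]
            rng = np.random.default_rng((params.seed * 3 + view_offset) % (2**31 - 1))
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset generation


def stratified_bridge_deltas(n: int) -> list[float]:
    """Bridge deviations cycling through the four classes (for balanced sets)."""
    classes = [-6.5, -3.0, 0.0, 2.5]  # broken, concave, straight, convex
    return [classes[i % 4] for i in range(n)]


def generate_participants(
    n: int,
    seed: int,
    overrides: dict | None = None,
    per_participant_overrides: list[dict] | None = None,
    render_images: bool = True,
    views: tuple = (View.FRONTAL, View.LATERAL, View.MENTAL),
) -> list[dict]:
    """In-memory dataset: n participants × the requested views.

    Returns a list of records ``{"id", "params", "annotations", "images"}``;
    annotations are exact projections, images schematic renders (or absent
    when ``render_images=False``).  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = np.random.default_rng(seed)
    face_seeds = root.integers(0, 2**31 - 1, size=n)
    records = []
    for i in range(n):
        ov = dict(overrides or {})
        if per_participant_overrides is not None:
            ov.update(per_participant_overrides[i])
        params = sample_face(int(face_seeds[i]), overrides=ov)
        rec: dict = {"id": f"participant_{i:03d}", "params": params, "annotations": {}, "images": {}}
        for view in views:
            view = View(view)
            rec["annotations"][view.value] = project(params, view)
            if render_images:
                rng = np.random.default_rng(int(face_seeds[i]) * 7 + {"frontal": 0, "lateral": 1, "mental": 2}[view.value])
                rec["images"][view.value] = render(params, view, rng=rng)
        records.append(rec)
    return records


def generate_dataset(n: int, seed: int, outdir, overrides: dict | None = None, **kwargs):
    """Write n participants × 3 views to disk and return the manifest.

    Layout: ``participant_XXX/{frontal,lateral,mental}.png`` +
    ``annotations.json``; a top-level ``manifest.csv`` records per-face
    parameters, file paths and the root seed.
    """
    import pandas as pd

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc
    records = generate_participants(n, seed, overrides=overrides, **kwargs)
    rows = []
    for rec in records:
        pdir = outdir / rec["id"]
        pdir.mkdir(exist_ok=True)
        paths = {}
        for view, img in rec["images"].items():
            path = pdir / f"{view}.png"
            Image.fromarray(img).save(path)
            paths[view] = str(path.relative_to(outdir))
        write_annotations_json(pdir / "annotations.json", rec["annotations"])
        p: FaceParams = rec["params"]
        rows.append(
            {
                "participant": rec["id"],
                "root_seed": seed,
                "face_seed": p.seed,
                "bridge_delta_mm": round(p.bridge_delta, 6),
                "hump_present": p.hump_present,
                "alpha_mm_per_px": round(p.alpha_eff, 6),
                "image_size": p.image_size,
                "tilt_deg": p.tilt_deg,
                **{f"path_{v}": paths.get(v, "") for v in ("frontal", "lateral", "mental")},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def manifest_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
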