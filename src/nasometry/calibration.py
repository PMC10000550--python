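"""Pixel → millimetre conversion for the three-view protocol.

The capture rig keeps the camera-to-subject distance fixed, so a single
mm-per-pixel ratio constant ``alpha`` relates pixel lengths to physical
lengths, modulated by

* a radial-distortion scale factor ``D = alpha * sum_i k_i * c^(2i)`` — an
  even polynomial in the radial distance ``c`` of the measured segment from
  the optical centre (``distortion=[1]`` means a distortion-free camera and
  ``D = alpha``);
* per-view unit lengths ``d_f``, ``d_s``, ``d_m`` — the pixel length of one
  common reference segment seen in the frontal, lateral (side) and mental
  views, which absorb small per-view scale differences; and
* a head-tilt coefficient ``T`` for the mental (basal) view, estimated from
  the ratio of the g–prn pixel distance in the mental view to that in the
  lateral view: the basal camera is aimed perpendicular to the g–prn line, so
  any tilt forward/back shortens the mental projection by cos(tilt).

Conversions:  frontal  d_mm = d_px * D
              lateral  d_mm = d_px * (d_s / d_f) * D
              mental   d_mm = d_px * (d_m / d_f) * D * T
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmarks import View

__all__ = ["CalibrationParams", "CalibrationError", "scale_factor", "tilt_coefficient", "to_millimetres"]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationParams:
    """Calibration inputs.  ``alpha`` is the mm-per-px ratio constant.

    ``distortion`` are the even-polynomial coefficients k_0..k_M (k_0 = 1,
    higher orders 0 for an ideal camera).  ``tilt_mode`` selects how the
    mental/lateral reference-length ratio becomes the tilt coefficient T:
    ``"ratio"`` (default) takes the ratio itself as cos(tilt); ``"literal"``
    evaluates cos(ratio) with the ratio read as radians.
    """

    alpha: float = 1.0
    distortion: list[float] = field(default_factory=lambda: [1.0])
    optical_center: tuple[float, float] = (0.0, 0.0)
    d_f: float = 1.0
    d_s: float = 1.0
    d_m: float = 1.0
    tilt_mode: str = "ratio"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise CalibrationError(f"alpha must be > 0, got {self.alpha}")
        for name in ("d_f", "d_s", "d_m"):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.tilt_mode not in {"ratio", "literal"}:
            raise CalibrationError(f"tilt_mode must be 'ratio' or 'literal', got {self.tilt_mode!r}")
        if not self.distortion:
            raise CalibrationError("distortion coefficient list must be non-empty")


def scale_factor(params: CalibrationParams, c: float = 0.0) -> float:
    """Distortion/scale factor D = alpha * sum_i k_i * c^(2i).

    ``c`` is the radial pixel distance of the measured segment's midpoint
    from the optical centre.  With ``distortion=[1]`` this is simply alpha.
    """
    if c < 0:
        raise CalibrationError(f"radial distance c must be >= 0, got {c}")
    c2 = c * c
    poly = 0.0
    term = 1.0
    for k in params.distortion:
        poly += k * term
        term *= c2
    d = params.alpha * poly
    if d <= 0:
        raise CalibrationError(f"non-positive scale factor D={d} (distortion polynomial ill-conditioned)")
    return d


def tilt_coefficient(d_mental: float, d_lateral: float, mode: str = "ratio") -> float:
    """Head-tilt coefficient T from the g–prn reference distances.

    ``mode="ratio"``: T = d_mental / d_lateral, the foreshortening cosine of
    the basal-view tilt (clamped to 1 with a warning if the projection
    nominally exceeds the true length).  ``mode="literal"``: T =
    cos(d_mental / d_lateral) with the dimensionless ratio read as radians.
    """
    if d_lateral <= 0:
        raise CalibrationError(f"lateral reference distance must be > 0, got {d_lateral}")
    if d_mental < 0:
        raise CalibrationError(f"mental reference distance must be >= 0, got {d_mental}")
    ratio = d_mental / d_lateral
    if mode == "literal":
        return math.cos(ratio)
    if mode == "ratio":
        if ratio > 1.0:
            if ratio <= 1.0 + 1e-9:  # float noise around an untilted head
                return 1.0
            warnings.warn(
                f"mental/lateral reference ratio {ratio:.4f} > 1 (a projection cannot exceed "
                "the true length); clamping T to 1",
                stacklevel=2,
            )
            return 1.0
        return ratio
    raise CalibrationError(f"unknown tilt mode {mode!r}")


def to_millimetres(
    d_px: float,
    view: View | str,
    params: CalibrationParams,
    T: float = 1.0,
    c: float = 0.0,
) -> float:
    """Convert a pixel length measured in ``view`` to millimetres."""
    view = View(view)
    D = scale_factor(params, c)
    if view is View.FRONTAL:
        return d_px * D
    if view is View.LATERAL:
        return d_px * (params.d_s / params.d_f) * D
    if view is View.MENTAL:
        return d_px * (params.d_m / params.d_f) * D * T
    raise CalibrationError(f"unknown view {view!r}")  # pragma: no cover
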