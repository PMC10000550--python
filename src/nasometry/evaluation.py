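"""Evaluation metrics: normalized mean error, failure rate, measurement error.

The landmark-localization error is the normalized mean error (NME): each
landmark's coordinate error is normalized per axis by the extent of the
evaluated shape (W, L, H — by default the bounding box of the ground-truth
landmark cloud, configurable to the image dimensions), and averaged over
landmarks.  Two forms are provided:

* ``conventional`` (default): (1/N) Σ √[(Δx/W)² + (Δy/L)² + (Δz/H)²] × 100,
  the standard percentage form under which results like "NME = 1.05%" are
  reported, and under which the failure rule (landmark NME > 8%) applies;
* ``literal``: (1/N) Σ [(Δx)²/W + (Δy)²/L + (Δz)²/H], a dimensional variant
  retained for fidelity with sources that print the un-rooted form.

Measurement error is the absolute deviation e = |d − d̂| between an actual
and a predicted measurement (mm or degrees), summarized per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .geometry import AngularMeasurement, LinearMeasurement
from .landmarks import Face3D, ViewAnnotation

__all__ = [
    "NMEReport",
    "MeasurementError",
    "nme",
    "bbox_dims",
    "measurement_errors",
    "evaluation_report",
    "FAILURE_THRESHOLD_PCT",
]

#: per-landmark NME above this percentage counts as a detection failure
FAILURE_THRESHOLD_PCT = 8.0


@dataclass
class NMEReport:
    per_landmark: dict[str, float]
    overall: float
    failure_rate: float  # percent of landmarks failing
    failures: list[str]
    dims: tuple
    mode: str
    n: int


def _points_of(obj) -> dict[str, np.ndarray]:
    if isinstance(obj, Face3D):
        return {pid: np.asarray(c, dtype=float) for pid, c in obj.points.items()}
    if isinstance(obj, ViewAnnotation):
        return {pid: np.array([p.u, p.v], dtype=float) for pid, p in obj.points.items()}
    return {pid: np.asarray(c, dtype=float) for pid, c in obj.items()}


def bbox_dims(truth) -> tuple:
    """Per-axis extent of the ground-truth landmark cloud (the default W, L, H)."""
    pts = np.array(list(_points_of(truth).values()))
    finite = np.all(np.isfinite(pts), axis=1)
    dims = pts[finite].max(axis=0) - pts[finite].min(axis=0)
    return tuple(float(d) for d in dims)


def nme(
    predicted,
    truth,
    dims: Sequence[float] | None = None,
    mode: str = "conventional",
    failure_threshold: float = FAILURE_THRESHOLD_PCT,
) -> NMEReport:
    """Normalized mean error between predicted and ground-truth landmarks.

    ``predicted`` and ``truth`` are Face3D, ViewAnnotation or plain mappings
    with identical point-id sets (an id mismatch raises, listing the
    symmetric difference).  ``dims`` are the per-axis normalizers (W, L[, H]);
    default = the truth bounding box.  Landmarks with any non-finite truth or
    predicted coordinate are skipped (they carry an explicit missing marker).
    """
    p = _points_of(predicted)
    t = _points_of(truth)
    if set(p) != set(t):
        diff = sorted(set(p) ^ set(t))
        raise ValueError(f"point-id sets differ; symmetric difference: {diff}")
    if mode not in {"conventional", "literal"}:
        raise ValueError(f"unknown NME mode {mode!r}")
    if dims is None:
        dims = bbox_dims(truth)
    dims_arr = np.asarray(dims, dtype=float)
    if np.any(dims_arr <= 0):
        raise ValueError(f"normalization dims must be > 0, got {dims}")

    per: dict[str, float] = {}
    for pid in sorted(t):
        tp, pp = t[pid], p[pid]
        if tp.shape != dims_arr.shape:
            raise ValueError(f"point {pid} has {tp.shape[0]} coords but {dims_arr.shape[0]} dims given")
        if not (np.all(np.isfinite(tp)) and np.all(np.isfinite(pp))):
            continue
        delta = pp - tp
        if mode == "conventional":
            per[pid] = float(np.sqrt(np.sum((delta / dims_arr) ** 2)) * 100.0)
        else:
            per[pid] = float(np.sum(delta**2 / dims_arr))
    if not per:
        raise ValueError("no landmark with complete coordinates to evaluate")
    values = np.array(list(per.values()))
    failures = sorted(pid for pid, v in per.items() if v > failure_threshold)
    return NMEReport(
        per_landmark=per,
        overall=float(values.mean()),
        failure_rate=100.0 * len(failures) / len(per),
        failures=failures,
        dims=tuple(float(d) for d in dims_arr),
        mode=mode,
        n=len(per),
    )


@dataclass
class MeasurementError:
    id: str
    actual: float
    predicted: float

    @property
    def e(self) -> float:
        return abs(self.actual - self.predicted)


def _as_value_map(report) -> dict[str, float]:
    if isinstance(report, Mapping):
        return {str(k): float(v) for k, v in report.items()}
    out = {}
    for m in report:
        if isinstance(m, (LinearMeasurement, AngularMeasurement)):
            if m.value is not None:
                out[m.id] = float(m.value)
        else:
            raise TypeError(f"unsupported measurement record {m!r}")
    return out


def measurement_errors(actual, predicted) -> tuple[list[MeasurementError], dict[str, float]]:
    """Absolute per-measurement errors e = |d − d̂| plus mean/sd summary.

    ``actual``/``predicted`` are measurement lists (missing values dropped)
    or id → value mappings; ids present in only one of the two raise.
    The summary sd is the sample standard deviation (ddof=1; 0 for n=1).
    """
    a = _as_value_map(actual)
    b = _as_value_map(predicted)
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise ValueError(f"measurement ids differ; symmetric difference: {diff}")
    errors = [MeasurementError(mid, a[mid], b[mid]) for mid in sorted(a)]
    es = np.array([err.e for err in errors])
    summary = {
        "mean": float(es.mean()) if len(es) else float("nan"),
        "sd": float(es.std(ddof=1)) if len(es) > 1 else 0.0,
        "n": len(es),
    }
    return errors, summary


def evaluation_report(cohort: Sequence[Mapping], out_csv=None, plot_path=None):
    """Cohort summary table (metric, value, n) analogous to a results table.

    ``cohort`` is a list of per-participant records, each with optional keys
    ``"nme"`` (an :class:`NMEReport`) and ``"errors"`` (list of
    :class:`MeasurementError`).  Returns a pandas DataFrame with columns
    exactly (metric, value, n); writes CSV / an error bar chart if paths are
    given.  Ordering is deterministic.
    """
    import pandas as pd

    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one participant")
    rows = []
    nmes = [rec["nme"] for rec in cohort if rec.get("nme") is not None]
    if nmes:
        rows.append({"metric": "nme_pct", "value": float(np.mean([r.overall for r in nmes])), "n": len(nmes)})
        total_landmarks = sum(r.n for r in nmes)
        total_failures = sum(len(r.failures) for r in nmes)
        rows.append(
            {"metric": "failure_rate_pct", "value": 100.0 * total_failures / total_landmarks, "n": total_landmarks}
        )
    per_id: dict[str, list[float]] = {}
    for rec in cohort:
        for err in rec.get("errors", []):
            per_id.setdefault(err.id, []).append(err.e)
    all_errors = [e for v in per_id.values() for e in v]
    if all_errors:
        rows.append({"metric": "mean_error", "value": float(np.mean(all_errors)), "n": len(all_errors)})
        rows.append(
            {
                "metric": "sd_error",
                "value": float(np.std(all_errors, ddof=1)) if len(all_errors) > 1 else 0.0,
                "n": len(all_errors),
            }
        )
        for mid in sorted(per_id):
            rows.append({"metric": f"mean_error_{mid}", "value": float(np.mean(per_id[mid])), "n": len(per_id[mid])})
    df = pd.DataFrame(rows, columns=["metric", "value", "n"])
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    if plot_path is not None and per_id:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ids = sorted(per_id)
        means = [np.mean(per_id[i]) for i in ids]
        sds = [np.std(per_id[i], ddof=1) if len(per_id[i]) > 1 else 0.0 for i in ids]
        fig, ax = plt.subplots(figsize=(8, 3.5))
        ax.bar(ids, means, yerr=sds, color="#4878a8")
        ax.set_ylabel("absolute error")
        ax.set_title("Per-measurement error (cohort mean ± sd)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
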