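"""Evaluation of estimated motion fields.

The accuracy metric is the mean registration error (MRE): the mean
Euclidean magnitude, over the source points, of the difference between
the true and the estimated per-point motion vectors,

    MRE = (1/n) sum_i | T_true,i - T_est,i |   (mm).

Method comparisons are summarized as a relative improvement percentage
versus a named baseline.  Fields are evaluated at the source cloud's
points; no interpolation onto other grids is performed.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import PointCloud
from .registration import RegistrationResult
from .synthetic import MotionField

__all__ = [
    "EvaluationReport",
    "mre",
    "per_point_error",
    "estimated_field",
    "improvement_pct",
    "write_report",
]


@dataclass
class EvaluationReport:
    mre: float  # mm
    per_point_error: np.ndarray  # (n,) mm
    improvement_pct: float | None = None  # vs a named baseline
    baseline_name: str | None = None
    trace: np.ndarray | None = None  # (iters,) per-iteration MRE


def _aligned(estimated: MotionField, truth: MotionField) -> tuple[np.ndarray, np.ndarray]:
    if estimated.n != truth.n:
        raise ValueError("fields must have the same number of points")
    a, b = estimated.displacements, truth.displacements
    if estimated.ids is None or truth.ids is None:
        if estimated.ids is not None or truth.ids is not None:
            raise ValueError("both fields must carry ids, or neither")
        return a, b
    order_e = np.argsort(estimated.ids)
    order_t = np.argsort(truth.ids)
    if not np.array_equal(estimated.ids[order_e], truth.ids[order_t]):
        raise ValueError("fields are not aligned: id sets differ")
    return a[order_e], b[order_t]


def per_point_error(estimated: MotionField, truth: MotionField) -> np.ndarray:
    """Per-point magnitudes |T_true - T_est| (mm), aligned by id."""
    a, b = _aligned(estimated, truth)
    return np.linalg.norm(b - a, axis=1)


def mre(estimated: MotionField, truth: MotionField) -> float:
    """Mean registration error (mm) between two id-aligned motion fields."""
    return float(per_point_error(estimated, truth).mean())


def estimated_field(result: RegistrationResult, source: PointCloud) -> MotionField:
    """Estimated displacements: deformed source minus original positions."""
    if result.deformed_source.n != source.n:
        raise ValueError("result does not correspond to this source cloud")
    return MotionField(result.deformed_source.points - source.points, ids=source.ids)


def improvement_pct(mre_baseline: float, mre_method: float) -> float:
    """Relative accuracy increase 100 (MRE_baseline - MRE_method) / MRE_baseline."""
    if mre_baseline <= 0:
        raise ValueError("baseline MRE must be positive")
    return 100.0 * (mre_baseline - mre_method) / mre_baseline


def write_report(report: EvaluationReport, out_dir: str | Path,
                 stem: str = "evaluation") -> None:
    """Write a report as a machine-readable summary plus data tables.

    ``<stem>.txt`` holds key: value lines, ``<stem>_errors.tsv`` the
    per-point error magnitudes, and ``<stem>_trace.tsv`` (when a trace is
    present) a two-column (iteration, MRE) table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = [f"mre_mm: {report.mre:.9g}"]
    if report.improvement_pct is not None:
        lines.append(f"baseline: {report.baseline_name or 'baseline'}")
        lines.append(f"improvement_pct: {report.improvement_pct:.9g}")
    (out_dir / f"{stem}.txt").write_text("\n".join(lines) + "\n")
    np.savetxt(out_dir / f"{stem}_errors.tsv", report.per_point_error,
               fmt="%.9g", header="error_mm", comments="# ")
    if report.trace is not None:
        table = np.column_stack([np.arange(len(report.trace)), report.trace])
        np.savetxt(out_dir / f"{stem}_trace.tsv", table, fmt=["%d", "%.9g"],
                   delimiter="\t", header="iteration\tmre_mm", comments="# ")
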