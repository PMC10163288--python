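"""Retrospective discrimination analysis and design-pipeline efficiency.

Efficiency of a design protocol is its filter pass rate divided by the
per-design compute cost expressed in CPU-second equivalents, with GPU time
converted at 100 CPU-s per GPU-s:

    efficiency = (n_pass / n_total) / (cpu_s + 100 * gpu_s)

Discrimination of binders from non-binders by a metric is summarised two
ways: the experimental success rate among the top fraction of designs
ranked by the metric, and the ROC curve / AUC with an explicit declaration
of whether lower metric values indicate binding (true for pae_interaction
and RMSD metrics, false for pLDDT) — there is no silent auto-flip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .filters import select_top_fraction
from .structio import DesignRecord

__all__ = [
    "EfficiencyReport",
    "RocResult",
    "efficiency",
    "success_rate_top_fraction",
    "roc_curve",
    "fold_improvement",
    "CPU_S_PER_GPU_S",
]

CPU_S_PER_GPU_S = 100.0


@dataclass(frozen=True)
class EfficiencyReport:
    """Pass counts, per-design compute cost and the resulting efficiency
    (passing designs per CPU-second equivalent)."""

    n_pass: int
    n_total: int
    cpu_s_per_design: float
    gpu_s_per_design: float
    conversion: float = CPU_S_PER_GPU_S

    def __post_init__(self) -> None:
        if not 0 <= self.n_pass <= self.n_total:
            raise ValueError("need 0 <= n_pass <= n_total")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.cpu_s_per_design < 0 or self.gpu_s_per_design < 0:
            raise ValueError("compute times must be non-negative")
        if self.cpu_s_per_design + self.gpu_s_per_design == 0:
            raise ValueError("at least one compute time must be positive")

    @property
    def pass_rate(self) -> float:
        return self.n_pass / self.n_total

    @property
    def cpu_s_equivalent(self) -> float:
        return self.cpu_s_per_design + self.conversion * self.gpu_s_per_design

    @property
    def efficiency(self) -> float:
        return self.pass_rate / self.cpu_s_equivalent


def efficiency(
    n_pass: int,
    n_total: int,
    cpu_s_per_design: float,
    gpu_s_per_design: float = 0.0,
    conversion: float = CPU_S_PER_GPU_S,
) -> EfficiencyReport:
    """Build an :class:`EfficiencyReport`; see the module docstring for the formula."""
    return EfficiencyReport(n_pass, n_total, cpu_s_per_design, gpu_s_per_design, conversion)


def _require_labels(records: Sequence[DesignRecord]) -> np.ndarray:
    labels = []
    for rec in records:
        if rec.label is None:
            raise ValueError(f"design {rec.design_id!r} has no experimental label")
        labels.append(bool(rec.label))
    return np.asarray(labels, dtype=bool)


def success_rate_top_fraction(
    records: Sequence[DesignRecord],
    metric: str,
    fraction: float,
    direction: str = "min",
) -> float:
    """Fraction of experimentally successful designs within the top
    ``fraction`` of designs ranked by ``metric``."""
    _require_labels(records)
    chosen = set(select_top_fraction(records, metric, fraction, direction))
    picked = [rec for rec in records if rec.design_id in chosen]
    return float(np.mean([rec.label for rec in picked]))


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(
    records: Sequence[DesignRecord], metric: str, direction: str = "min"
) -> RocResult:
    """ROC curve and trapezoid AUC of ``metric`` against the labels.

    ``direction='min'`` declares that lower metric values indicate binding;
    equal scores are grouped into a single step so ties cost AUC rather
    than inflating it.
    """
    labels = _require_labels(records)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes present")
    for rec in records:
        if metric not in rec.metrics:
            raise ValueError(f"design {rec.design_id!r} lacks metric {metric!r}")
    values = np.array([rec.metrics[metric] for rec in records], dtype=float)
    if direction == "min":
        scores = -values
    elif direction == "max":
        scores = values
    else:
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def fold_improvement(
    efficiency_a: float | Sequence[float], efficiency_b: float | Sequence[float]
) -> float:
    """Ratio a/b; for per-target vectors, the arithmetic mean of per-target ratios."""
    a = np.atleast_1d(np.asarray(efficiency_a, dtype=float))
    b = np.atleast_1d(np.asarray(efficiency_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("per-target efficiency vectors must have equal length")
    if np.any(b <= 0):
        raise ValueError("denominator efficiencies must be positive")
    return float(np.mean(a / b))


def format_report(rows: Sequence[tuple[str, float]]) -> str:
    """Simple two-column TSV report, values at 6 significant digits."""
    buf = io.StringIO()
    buf.write("quantity\tvalue\n")
    for name, value in rows:
        buf.write(f"{name}\t{value:.6g}\n")
    return buf.getvalue()
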