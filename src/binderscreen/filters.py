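"""Threshold filtering, pareto-front selection and top-fraction selection.

The two-stage screen keys on two metrics: ``pae_interaction`` strictly
below 10 A and ``af2_complex_rmsd`` strictly below 5 A.  Thresholds are
written with strict inequality because that is how the screen is defined;
strictness and direction are configurable per criterion.  Designs missing
a required metric fail closed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .structio import DesignRecord

__all__ = [
    "Criterion",
    "FilterCriteria",
    "FilterVerdict",
    "apply_filter",
    "pareto_front",
    "pareto_select",
    "select_top_fraction",
]

_DIRECTIONS = ("below", "above")


@dataclass(frozen=True)
class Criterion:
    """A single threshold on a named metric."""

    metric: str
    bound: float
    direction: str = "below"
    strict: bool = True

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"direction must be one of {_DIRECTIONS}, got {self.direction!r}")

    def passes(self, value: float) -> bool:
        if self.direction == "below":
            return value < self.bound if self.strict else value <= self.bound
        return value > self.bound if self.strict else value >= self.bound


@dataclass
class FilterCriteria:
    """An ordered set of criteria, optionally validated against a metric schema."""

    criteria: list[Criterion]
    schema: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.schema is not None:
            self.schema = frozenset(self.schema)
            unknown = [c.metric for c in self.criteria if c.metric not in self.schema]
            if unknown:
                raise ValueError(f"criteria reference unknown metrics: {unknown}")

    @classmethod
    def default(cls) -> "FilterCriteria":
        """The standard two-metric screen: pae_interaction < 10, af2_complex_rmsd < 5 A."""
        return cls(
            [
                Criterion("pae_interaction", 10.0, "below", strict=True),
                Criterion("af2_complex_rmsd", 5.0, "below", strict=True),
            ]
        )

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping[str, Mapping[str, object]],
        schema: Iterable[str] | None = None,
    ) -> "FilterCriteria":
        """Build criteria from a plain dict, e.g. parsed YAML/JSON::

            {"pae_interaction": {"bound": 10, "direction": "below", "strict": true}}
        """
        crits = []
        for metric, c in mapping.items():
            crits.append(
                Criterion(
                    metric=metric,
                    bound=float(c["bound"]),
                    direction=str(c.get("direction", "below")),
                    strict=bool(c.get("strict", True)),
                )
            )
        return cls(crits, schema=frozenset(schema) if schema is not None else None)

    @classmethod
    def from_yaml(cls, text: str, schema: Iterable[str] | None = None) -> "FilterCriteria":
        return cls.from_mapping(yaml.safe_load(text), schema=schema)


@dataclass(frozen=True)
class FilterVerdict:
    design_id: str
    passed: bool
    failed_criteria: tuple[str, ...] = ()
    missing_metrics: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = not self.failed_criteria and not self.missing_metrics
        if self.passed != expected:
            raise ValueError("pass flag inconsistent with failure lists")


def apply_filter(
    records: Sequence[DesignRecord], criteria: FilterCriteria
) -> list[FilterVerdict]:
    """One verdict per record, order preserved; missing metrics fail closed."""
    if not records:
        raise ValueError("no records to filter")
    verdicts = []
    for rec in records:
        failed: list[str] = []
        missing: list[str] = []
        for crit in criteria.criteria:
            if crit.metric not in rec.metrics:
                missing.append(crit.metric)
            elif not crit.passes(rec.metrics[crit.metric]):
                failed.append(crit.metric)
        verdicts.append(
            FilterVerdict(
                design_id=rec.design_id,
                passed=not failed and not missing,
                failed_criteria=tuple(failed),
                missing_metrics=tuple(missing),
            )
        )
    return verdicts


def _objective_matrix(
    records: Sequence[DesignRecord], objectives: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Objective values oriented so smaller is always better."""
    cols = []
    for metric, direction in objectives:
        if direction not in ("min", "max"):
            raise ValueError(f"objective direction must be 'min' or 'max', got {direction!r}")
        vals = []
        for rec in records:
            if metric not in rec.metrics:
                raise ValueError(f"design {rec.design_id!r} lacks objective metric {metric!r}")
            vals.append(rec.metrics[metric])
        col = np.asarray(vals, dtype=float)
        cols.append(col if direction == "min" else -col)
    return np.column_stack(cols)


def pareto_front(
    records: Sequence[DesignRecord], objectives: Sequence[tuple[str, str]]
) -> set[str]:
    """The non-dominated set under the given ``(metric, 'min'|'max')`` objectives.

    A record is excluded iff some other record is at least as good on every
    objective and strictly better on at least one.
    """
    if not objectives:
        raise ValueError("at least one objective is required")
    if not records:
        return set()
    vals = _objective_matrix(records, objectives)
    n = vals.shape[0]
    # pairwise domination via broadcasting: dom[j, i] == j dominates i
    le = (vals[:, None, :] <= vals[None, :, :]).all(axis=2)
    lt = (vals[:, None, :] < vals[None, :, :]).any(axis=2)
    dominated = (le & lt).any(axis=0)
    return {records[i].design_id for i in range(n) if not dominated[i]}


def pareto_select(
    records: Sequence[DesignRecord],
    objectives: Sequence[tuple[str, str]],
    quota: int,
    tie_break_metric: str = "pae_interaction",
) -> list[str]:
    """Select exactly ``quota`` designs by iterative pareto-front peeling.

    Whole fronts are admitted while they fit; the front that would overflow
    the quota is admitted partially, in ascending order of
    ``tie_break_metric`` (design_id breaks remaining ties).
    """
    if quota <= 0:
        raise ValueError("quota must be positive")
    if quota > len(records):
        raise ValueError(f"quota {quota} exceeds number of records {len(records)}")

    def tie_key(rec: DesignRecord) -> tuple[float, str]:
        return (rec.metrics.get(tie_break_metric, math.inf), rec.design_id)

    remaining = {rec.design_id: rec for rec in records}
    selected: list[str] = []
    while len(selected) < quota:
        front_ids = pareto_front(list(remaining.values()), objectives)
        front = sorted((remaining[d] for d in front_ids), key=tie_key)
        room = quota - len(selected)
        for rec in front[:room]:
            selected.append(rec.design_id)
        for rec in front:
            del remaining[rec.design_id]
    return selected


def select_top_fraction(
    records: Sequence[DesignRecord],
    metric: str,
    fraction: float,
    direction: str = "min",
) -> list[str]:
    """The best ``ceil(fraction * n)`` designs by one metric.

    Ties on the metric are broken by design_id lexicographic order so that
    the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if direction not in ("min", "max"):
        raise ValueError(f"direction must be 'min' or 'max', got {direction!r}")
    for rec in records:
        if metric not in rec.metrics:
            raise ValueError(f"design {rec.design_id!r} lacks metric {metric!r}")
    k = math.ceil(fraction * len(records))
    sign = 1.0 if direction == "min" else -1.0
    ranked = sorted(records, key=lambda r: (sign * r.metrics[metric], r.design_id))
    return [rec.design_id for rec in ranked[:k]]
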