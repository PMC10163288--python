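"""Threshold filtering, pareto selection and top-fraction selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binderscreen.filters import (
    Criterion,
    FilterCriteria,
    apply_filter,
    pareto_front,
    pareto_select,
    select_top_fraction,
)
from binderscreen.structio import DesignRecord


def recs_from_values(values, metric="pae_interaction"):
    return [
        DesignRecord(f"d{i:03d}", metrics={metric: float(v)}) for i, v in enumerate(values)
    ]


class TestApplyFilter:
    def test_default_screen_passes_good_design(self):
        rec = DesignRecord("d1", metrics={"pae_interaction": 4.5, "af2_complex_rmsd": 1.2})
        (v,) = apply_filter([rec], FilterCriteria.default())
        assert v.passed and not v.failed_criteria and not v.missing_metrics

    @pytest.mark.parametrize(
        "metrics_dict, failed",
        [
            ({"pae_interaction": 10.0, "af2_complex_rmsd": 1.0}, ("pae_interaction",)),
            ({"pae_interaction": 4.0, "af2_complex_rmsd": 5.0}, ("af2_complex_rmsd",)),
            ({"pae_interaction": 10.0, "af2_complex_rmsd": 5.0},
             ("pae_interaction", "af2_complex_rmsd")),
        ],
    )
    def test_boundary_values_fail_strict_thresholds(self, metrics_dict, failed):
        (v,) = apply_filter([DesignRecord("d", metrics=metrics_dict)], FilterCriteria.default())
        assert not v.passed
        assert v.failed_criteria == failed

    def test_inclusive_boundary_passes(self):
        crit = FilterCriteria([Criterion("pae_interaction", 10.0, "below", strict=False)])
        (v,) = apply_filter([DesignRecord("d", metrics={"pae_interaction": 10.0})], crit)
        assert v.passed

    def test_missing_metric_fails_closed(self):
        rec = DesignRecord("d1", metrics={"pae_interaction": 4.0})
        (v,) = apply_filter([rec], FilterCriteria.default())
        assert not v.passed
        assert v.missing_metrics == ("af2_complex_rmsd",)

    def test_schema_validation_at_construction(self):
        with pytest.raises(ValueError, match="unknown metrics"):
            FilterCriteria(
                [Criterion("no_such_metric", 1.0)],
                schema={"pae_interaction", "af2_complex_rmsd"},
            )

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            apply_filter([], FilterCriteria.default())

    @given(bound=st.floats(0.0, 20.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pass_set_shrinks_as_threshold_tightens(self, bound):
        rng = np.random.default_rng(7)
        recs = recs_from_values(rng.uniform(0, 20, size=40))
        loose = FilterCriteria([Criterion("pae_interaction", bound)])
        tight = FilterCriteria([Criterion("pae_interaction", bound * 0.7)])
        pass_loose = {v.design_id for v in apply_filter(recs, loose) if v.passed}
        pass_tight = {v.design_id for v in apply_filter(recs, tight) if v.passed}
        assert pass_tight <= pass_loose

    def test_yaml_criteria_roundtrip(self):
        text = "pae_interaction: {bound: 10, direction: below, strict: true}\n"
        crit = FilterCriteria.from_yaml(text)
        assert crit.criteria[0] == Criterion("pae_interaction", 10.0, "below", True)


def pareto_oracle(records, objectives):
    """All-pairs O(n^2) domination check, written independently."""
    def oriented(rec):
        out = []
        for metric, direction in objectives:
            v = rec.metrics[metric]
            out.append(v if direction == "min" else -v)
        return out

    selected = set()
    for a in records:
        va = oriented(a)
        dominated = False
        for b in records:
            if a is b:
                continue
            vb = oriented(b)
            if all(x <= y for x, y in zip(vb, va)) and any(x < y for x, y in zip(vb, va)):
                dominated = True
                break
        if not dominated:
            selected.add(a.design_id)
    return selected


class TestPareto:
    def test_single_record_selected(self):
        recs = [DesignRecord("only", metrics={"a": 1.0})]
        assert pareto_front(recs, [("a", "min")]) == {"only"}

    def test_simple_domination(self):
        recs = [
            DesignRecord("good", metrics={"a": 1.0, "b": 1.0}),
            DesignRecord("bad", metrics={"a": 2.0, "b": 2.0}),
        ]
        assert pareto_front(recs, [("a", "min"), ("b", "min")]) == {"good"}

    def test_direction_awareness(self):
        recs = [
            DesignRecord("hi", metrics={"a": 5.0}),
            DesignRecord("lo", metrics={"a": 1.0}),
        ]
        assert pareto_front(recs, [("a", "max")]) == {"hi"}

    def test_matches_all_pairs_oracle(self, rng):
        objectives = [("a", "min"), ("b", "max"), ("c", "min")]
        for _ in range(20):
            recs = [
                DesignRecord(
                    f"d{i}",
                    metrics={
                        "a": float(rng.integers(0, 6)),
                        "b": float(rng.integers(0, 6)),
                        "c": float(rng.integers(0, 6)),
                    },
                )
                for i in range(50)
            ]
            assert pareto_front(recs, objectives) == pareto_oracle(recs, objectives)

    def test_front_never_contains_dominated_record(self, rng):
        recs = [
            DesignRecord(f"d{i}", metrics={"a": float(rng.normal()), "b": float(rng.normal())})
            for i in range(60)
        ]
        objectives = [("a", "min"), ("b", "min")]
        front = pareto_front(recs, objectives)
        by_id = {r.design_id: r for r in recs}
        for fid in front:
            fa, fb = by_id[fid].metrics["a"], by_id[fid].metrics["b"]
            for r in recs:
                assert not (
                    r.metrics["a"] <= fa and r.metrics["b"] <= fb
                    and (r.metrics["a"] < fa or r.metrics["b"] < fb)
                )

    def test_empty_objectives_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([DesignRecord("d", metrics={"a": 1.0})], [])


class TestParetoSelect:
    def make_records(self, rng, n=40):
        return [
            DesignRecord(
                f"d{i:02d}",
                metrics={
                    "a": float(rng.normal()),
                    "b": float(rng.normal()),
                    "pae_interaction": float(rng.uniform(0, 20)),
                },
            )
            for i in range(n)
        ]

    def test_quota_equals_n_returns_all(self, rng):
        recs = self.make_records(rng, 15)
        out = pareto_select(recs, [("a", "min"), ("b", "min")], quota=15)
        assert sorted(out) == sorted(r.design_id for r in recs)

    def test_quota_equal_first_front(self, rng):
        recs = self.make_records(rng)
        objectives = [("a", "min"), ("b", "min")]
        front = pareto_front(recs, objectives)
        out = pareto_select(recs, objectives, quota=len(front))
        assert set(out) == front

    def test_peeling_structure(self, rng):
        """Selection is the union of leading fronts plus a tie-break-ordered
        prefix of the next front (verified against an explicit peeling oracle)."""
        recs = self.make_records(rng)
        objectives = [("a", "min"), ("b", "min")]
        quota = 23
        out = pareto_select(recs, objectives, quota)
        assert len(out) == quota and len(set(out)) == quota
        remaining = list(recs)
        taken = []
        while True:
            front = pareto_oracle(remaining, objectives)
            if len(taken) + len(front) > quota:
                by_id = {r.design_id: r for r in remaining}
                partial = sorted(
                    front, key=lambda d: (by_id[d].metrics["pae_interaction"], d)
                )[: quota - len(taken)]
                taken.extend(partial)
                break
            taken.extend(sorted(front))
            remaining = [r for r in remaining if r.design_id not in front]
        assert set(out) == set(taken)

    def test_bad_quota(self, rng):
        recs = self.make_records(rng, 5)
        with pytest.raises(ValueError):
            pareto_select(recs, [("a", "min")], 0)
        with pytest.raises(ValueError):
            pareto_select(recs, [("a", "min")], 6)


class TestTopFraction:
    def test_fraction_one_selects_all(self, rng):
        recs = recs_from_values(rng.uniform(0, 10, 12))
        assert len(select_top_fraction(recs, "pae_interaction", 1.0)) == 12

    def test_smallest_selected_when_minimizing(self):
        recs = recs_from_values([5, 1, 9, 3, 7, 2, 8, 4, 6, 0])
        out = select_top_fraction(recs, "pae_interaction", 0.2, "min")
        assert out == ["d009", "d001"]

    def test_matches_sort_oracle_and_size(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            frac = float(rng.uniform(0.05, 1.0))
            recs = recs_from_values(rng.normal(size=n))
            out = select_top_fraction(recs, "pae_interaction", frac, "max")
            expected = sorted(
                recs, key=lambda r: (-r.metrics["pae_interaction"], r.design_id)
            )[: math.ceil(frac * n)]
            assert out == [r.design_id for r in expected]
            assert len(out) == math.ceil(frac * n)

    def test_metric_absent_rejected(self):
        recs = [DesignRecord("d1", metrics={"x": 1.0}), DesignRecord("d2", metrics={})]
        with pytest.raises(ValueError, match="d2"):
            select_top_fraction(recs, "x", 0.5)
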