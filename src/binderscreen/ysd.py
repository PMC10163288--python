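"""SC50 estimation from yeast-surface-display titration sequencing counts.

A displayed design's binding is read out by fluorescence-activated sorting
at a series of target concentrations; deep sequencing of each collected
pool gives per-design read counts.  The fraction of expressing cells
collected at concentration ``c`` is modelled as a one-site saturable
isotherm

    f(c) = f_max * c / (c + SC50)

and SC50 — the concentration at which half of the expressing cells are
collected — is recovered by least squares with the concentration axis
parameterised in log space.  Designs with SC50 better (lower) than 4 uM
are called successes.

The estimator here is stated explicitly rather than imported from any
published pipeline: collection fractions are frequency ratios against an
expression-only reference sort, rescaled by total collected cell counts
when those are recorded; avidity sorts (multivalent target presentation
used as an enrichment gate for weak binders) are excluded from fitting
because avidity distorts the monovalent concentration dependence.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SortSpec",
    "SortSeries",
    "SC50Estimate",
    "NoExpressionError",
    "collection_fractions",
    "estimate_sc50",
    "estimate_from_series",
    "call_success",
    "read_sort_manifest",
    "write_sort_manifest",
    "read_count_matrix",
    "write_count_matrix",
    "SUCCESS_THRESHOLD_UM",
]

SUCCESS_THRESHOLD_UM = 4.0


class NoExpressionError(ValueError):
    """The design has zero reads in the expression reference sort."""


@dataclass(frozen=True)
class SortSpec:
    """One sort's metadata.

    ``concentration`` is the monovalent target concentration in uM and is
    ``None`` for the expression-only sort.  ``total_cells_collected`` is
    optional; when absent, collection fractions fall back to plain
    frequency ratios.
    """

    sort_id: str
    concentration: float | None = None
    avidity: bool = False
    total_reads: int = 0
    total_cells_collected: int | None = None

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.total_cells_collected is not None and self.total_cells_collected <= 0:
            raise ValueError("total_cells_collected must be positive when given")


@dataclass
class SortSeries:
    """Per-design read counts across a shared list of sorts."""

    design_id: str
    counts: dict[str, int]
    sorts: list[SortSpec]

    def __post_init__(self) -> None:
        known = {s.sort_id for s in self.sorts}
        for sid, cnt in self.counts.items():
            if sid not in known:
                raise ValueError(f"count for unknown sort {sid!r}")
            if cnt < 0:
                raise ValueError(f"negative count for sort {sid!r}")

    def spec(self, sort_id: str) -> SortSpec:
        for s in self.sorts:
            if s.sort_id == sort_id:
                return s
        raise KeyError(sort_id)


@dataclass(frozen=True)
class SC50Estimate:
    """Fit result; ``sc50`` (uM) is present iff the fit converged in range."""

    sc50: float | None
    f_max: float
    residual: float
    status: str  # converged | no_binding | out_of_range

    def __post_init__(self) -> None:
        if (self.status == "converged") != (self.sc50 is not None):
            raise ValueError("sc50 must be present iff status is 'converged'")
        if self.sc50 is not None and self.sc50 <= 0:
            raise ValueError("sc50 must be positive when present")


def collection_fractions(
    series: SortSeries, reference_sort: str
) -> dict[float, float]:
    """Per-concentration collected fraction of expressing cells.

    fraction(c) = (freq in sort * cells collected in sort)
                / (freq in reference * cells collected in reference)

    clipped to [0, 1]; when either sort lacks a cell total the ratio falls
    back to plain frequencies.  Avidity sorts and the reference itself are
    excluded.  Raises :class:`NoExpressionError` when the design has zero
    reads in the reference sort.
    """
    ref = series.spec(reference_sort)
    ref_count = series.counts.get(reference_sort, 0)
    if ref_count == 0:
        raise NoExpressionError(
            f"design {series.design_id!r} has no reads in reference sort {reference_sort!r}"
        )
    ref_freq = ref_count / ref.total_reads
    out: dict[float, float] = {}
    for s in series.sorts:
        if s.sort_id == reference_sort or s.avidity or s.concentration is None:
            continue
        freq = series.counts.get(s.sort_id, 0) / s.total_reads
        if s.total_cells_collected is not None and ref.total_cells_collected is not None:
            frac = (freq * s.total_cells_collected) / (ref_freq * ref.total_cells_collected)
        else:
            frac = freq / ref_freq
        out[s.concentration] = float(min(max(frac, 0.0), 1.0))
    return out


def _isotherm(c: np.ndarray, f_max: float, sc50: float, hill: float = 1.0) -> np.ndarray:
    ch = c**hill
    return f_max * ch / (ch + sc50**hill)


def estimate_sc50(
    fractions: Mapping[float, float],
    *,
    no_binding_max_fraction: float = 0.1,
    out_of_range_factor: float = 10.0,
    hill_slope: bool = False,
) -> SC50Estimate:
    """Fit the saturable isotherm to collected fractions.

    Requires at least 3 distinct positive concentrations.  Returns status
    ``no_binding`` when the maximal observed fraction is below
    ``no_binding_max_fraction`` and ``out_of_range`` when the fitted SC50
    exceeds ``out_of_range_factor`` times the highest tested concentration.
    ``hill_slope=True`` adds a free Hill exponent to the model.
    """
    conc = np.array(sorted(c for c in fractions if c > 0), dtype=float)
    if len(conc) < 3:
        raise ValueError(f"need >= 3 distinct positive concentrations, got {len(conc)}")
    obs = np.array([fractions[c] for c in conc], dtype=float)
    if obs.max() < no_binding_max_fraction:
        return SC50Estimate(sc50=None, f_max=float(obs.max()), residual=0.0, status="no_binding")

    logc = np.log10(conc)
    lo, hi = logc.min() - 6.0, logc.max() + 6.0

    # initial guess: f_max from the plateau, SC50 where f crosses half-plateau
    f0 = min(max(obs.max(), 1e-3), 1.0)
    half = f0 / 2.0
    i0 = int(np.argmin(np.abs(obs - half)))
    x0_log_sc50 = float(np.clip(logc[i0], lo, hi))

    if hill_slope:
        def resid(p: np.ndarray) -> np.ndarray:
            fmax, log_sc50, h = p
            return _isotherm(conc, fmax, 10.0**log_sc50, h) - obs

        p0 = [f0, x0_log_sc50, 1.0]
        bounds = ([0.0, lo, 0.2], [1.0, hi, 5.0])
    else:
        def resid(p: np.ndarray) -> np.ndarray:
            fmax, log_sc50 = p
            return _isotherm(conc, fmax, 10.0**log_sc50) - obs

        p0 = [f0, x0_log_sc50]
        bounds = ([0.0, lo], [1.0, hi])

    fit = least_squares(resid, p0, bounds=bounds, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    f_max = float(fit.x[0])
    sc50 = float(10.0 ** fit.x[1])
    residual = float(np.sqrt(np.mean(fit.fun**2)))
    if sc50 > out_of_range_factor * conc.max():
        return SC50Estimate(sc50=None, f_max=f_max, residual=residual, status="out_of_range")
    return SC50Estimate(sc50=sc50, f_max=f_max, residual=residual, status="converged")


def estimate_from_series(
    series: SortSeries, reference_sort: str, **kwargs
) -> SC50Estimate:
    """Convenience path counts -> fractions -> fit; zero expression maps to no_binding."""
    try:
        fractions = collection_fractions(series, reference_sort)
    except NoExpressionError:
        return SC50Estimate(sc50=None, f_max=0.0, residual=0.0, status="no_binding")
    return estimate_sc50(fractions, **kwargs)


def call_success(estimate: SC50Estimate, threshold: float = SUCCESS_THRESHOLD_UM) -> bool:
    """True iff the fit converged and SC50 is strictly better (lower) than threshold."""
    return estimate.status == "converged" and estimate.sc50 < threshold


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_sort_manifest(tsv_text: str) -> list[SortSpec]:
    """Manifest columns: sort_id, concentration_uM, avidity, total_reads,
    total_cells_collected (optional cells; empty concentration = expression sort)."""
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str, keep_default_na=False)
    specs = []
    for _, row in df.iterrows():
        conc = row["concentration_uM"].strip()
        cells = row.get("total_cells_collected", "").strip()
        specs.append(
            SortSpec(
                sort_id=row["sort_id"],
                concentration=float(conc) if conc else None,
                avidity=row["avidity"].strip().lower() in ("true", "1", "yes"),
                total_reads=int(row["total_reads"]),
                total_cells_collected=int(cells) if cells else None,
            )
        )
    return specs


def write_sort_manifest(specs: Sequence[SortSpec]) -> str:
    lines = ["sort_id\tconcentration_uM\tavidity\ttotal_reads\ttotal_cells_collected"]
    for s in specs:
        conc = "" if s.concentration is None else f"{s.concentration:.6g}"
        cells = "" if s.total_cells_collected is None else str(s.total_cells_collected)
        lines.append(f"{s.sort_id}\t{conc}\t{s.avidity}\t{s.total_reads}\t{cells}")
    return "\n".join(lines) + "\n"


def read_count_matrix(tsv_text: str, sorts: Sequence[SortSpec]) -> list[SortSeries]:
    """Count matrix: rows = design_id, one column per sort_id."""
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype={"design_id": str})
    if "design_id" not in df.columns:
        raise ValueError("count matrix lacks a design_id column")
    sort_ids = [c for c in df.columns if c != "design_id"]
    series = []
    for _, row in df.iterrows():
        counts = {sid: int(row[sid]) for sid in sort_ids}
        series.append(SortSeries(design_id=row["design_id"], counts=counts, sorts=list(sorts)))
    return series


def write_count_matrix(series_list: Sequence[SortSeries]) -> str:
    if not series_list:
        raise ValueError("no series to write")
    sort_ids = [s.sort_id for s in series_list[0].sorts]
    lines = ["design_id\t" + "\t".join(sort_ids)]
    for series in series_list:
        cells = [str(series.counts.get(sid, 0)) for sid in sort_ids]
        lines.append(series.design_id + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
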