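"""Campaign orchestration, the prediction-request contract and the
sequence-design / relax cycle.

Two pieces of the production protocol are represented here as *contracts*
rather than computations:

* :class:`PredictionRequest` — the payload handed to a structure predictor
  run in "initial guess" mode: per-chain sequences, the full designed
  C-alpha coordinates used to seed the first recycle, and a flag marking
  target chains to be supplied as templates.  No inference happens in this
  package; the request only needs to be complete, validated and
  round-trippable.
* :func:`mpnn_fr_cycle` — the alternation of inverse-folding sequence
  design on the binder (with its sequence masked) and whole-complex
  relaxation.  Designer and relaxer are pluggable callables; deterministic
  mocks are shipped so the orchestration is testable without any external
  design or relax program.

:func:`run_campaign` wires the whole screen together: generate or load
designs, compute metrics, apply filter criteria and (when labels exist)
produce the discrimination report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import evalx, metrics, synth
from .filters import FilterCriteria, FilterVerdict, apply_filter
from .structio import (
    ONE_TO_THREE,
    ChainStructure,
    ComplexStructure,
    DesignRecord,
    read_confidence,
    read_structure,
    write_score_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionRequest",
    "build_prediction_request",
    "CycleState",
    "mpnn_fr_cycle",
    "MockDesigner",
    "MockRelaxer",
    "CampaignResult",
    "run_campaign",
]


# ---------------------------------------------------------------------------
# Prediction-request contract
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionRequest:
    """Inputs for an initial-guess complex prediction.

    ``initial_guess_coords`` seeds the predictor's first recycle with the
    designed coordinates instead of zeros; ``target_template`` marks which
    chains are supplied as structural templates.  ``reduced_extra_msa``
    records the speed-oriented predictor configuration; it has no behaviour
    on this side of the contract.
    """

    sequences: dict[str, str]
    initial_guess_coords: dict[str, np.ndarray]
    target_template: dict[str, bool]
    recycle_init: bool = True
    reduced_extra_msa: bool = True

    def __post_init__(self) -> None:
        if set(self.sequences) != set(self.initial_guess_coords) or set(
            self.sequences
        ) != set(self.target_template):
            raise ValueError("sequences, coords and template flags must cover the same chains")
        for cid, seq in self.sequences.items():
            coords = np.asarray(self.initial_guess_coords[cid], dtype=float)
            if coords.shape != (len(seq), 3):
                raise ValueError(
                    f"chain {cid!r}: sequence length {len(seq)} does not match "
                    f"coordinate shape {coords.shape}"
                )

    @property
    def n_positions(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "sequences": self.sequences,
                "initial_guess_coords": {
                    cid: np.asarray(xyz, dtype=float).tolist()
                    for cid, xyz in self.initial_guess_coords.items()
                },
                "target_template": self.target_template,
                "recycle_init": self.recycle_init,
                "reduced_extra_msa": self.reduced_extra_msa,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "PredictionRequest":
        d = json.loads(text)
        return cls(
            sequences=dict(d["sequences"]),
            initial_guess_coords={
                cid: np.asarray(xyz, dtype=float)
                for cid, xyz in d["initial_guess_coords"].items()
            },
            target_template=dict(d["target_template"]),
            recycle_init=bool(d["recycle_init"]),
            reduced_extra_msa=bool(d["reduced_extra_msa"]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionRequest):
            return NotImplemented
        return (
            self.sequences == other.sequences
            and self.target_template == other.target_template
            and self.recycle_init == other.recycle_init
            and self.reduced_extra_msa == other.reduced_extra_msa
            and set(self.initial_guess_coords) == set(other.initial_guess_coords)
            and all(
                np.allclose(self.initial_guess_coords[c], other.initial_guess_coords[c])
                for c in self.initial_guess_coords
            )
        )


def build_prediction_request(
    designed: ComplexStructure | ChainStructure,
    sequences: Mapping[str, str] | None = None,
) -> PredictionRequest:
    """Assemble the initial-guess payload for a designed complex.

    Sequences default to those read off the structure's residue names.  A
    bare :class:`ChainStructure` is accepted as the binder-only degenerate
    case; then no chain is templated and a warning is logged.
    """
    if isinstance(designed, ChainStructure):
        logger.warning(
            "binder-only structure: no target chains, target_template is vacuously false"
        )
        chains = [designed]
        template = {designed.chain_id: False}
    else:
        chains = [designed.binder, *designed.targets]
        template = {designed.binder_chain_id: False}
        for tid in designed.target_chain_ids:
            template[tid] = True
    seqs = {c.chain_id: c.sequence for c in chains}
    if sequences is not None:
        for cid, seq in sequences.items():
            if cid not in seqs:
                raise ValueError(f"sequence provided for unknown chain {cid!r}")
            if len(seq) != len(seqs[cid]):
                raise ValueError(
                    f"chain {cid!r}: provided sequence length {len(seq)} does not match "
                    f"structure length {len(seqs[cid])}"
                )
            seqs[cid] = seq
    coords = {c.chain_id: c.ca_coords.copy() for c in chains}
    return PredictionRequest(sequences=seqs, initial_guess_coords=coords, target_template=template)


# ---------------------------------------------------------------------------
# Design / relax cycle
# ---------------------------------------------------------------------------

Designer = Callable[[ComplexStructure], str]
Relaxer = Callable[[ComplexStructure], ComplexStructure]


@dataclass
class CycleState:
    """State after running the design/relax cycle."""

    iteration: int
    structure: ComplexStructure
    binder_sequence: str
    log: list[dict] = field(default_factory=list)


def _structure_digest(cs: ComplexStructure) -> str:
    h = hashlib.sha1()
    for chain in cs.chains:
        h.update(chain.chain_id.encode())
        h.update(np.ascontiguousarray(np.round(chain.ca_coords, 6)).tobytes())
    return h.hexdigest()[:12]


def _masked_binder(cs: ComplexStructure) -> ComplexStructure:
    masked = cs.copy()
    masked.binder.residue_names = ["UNK"] * len(masked.binder)
    return masked


def mpnn_fr_cycle(
    initial: ComplexStructure,
    designer: Designer,
    relaxer: Relaxer,
    n_cycles: int = 3,
) -> CycleState:
    """Run ``n_cycles`` of binder sequence design -> threading -> relaxation.

    Per cycle the designer sees the complex with the binder sequence masked
    and returns a new binder sequence of identical length; the sequence is
    threaded onto the binder and the whole complex is relaxed.  The relaxed
    complex feeds the next cycle.  Target chain sequences are never
    modified; a designer or relaxer violating its contract raises.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    state = CycleState(
        iteration=0,
        structure=initial.copy(),
        binder_sequence=initial.binder.sequence,
        log=[],
    )
    target_names = {tid: list(initial.chain(tid).residue_names) for tid in initial.target_chain_ids}
    for it in range(1, n_cycles + 1):
        seq = designer(_masked_binder(state.structure))
        if len(seq) != len(state.structure.binder):
            raise ValueError(
                f"designer returned sequence of length {len(seq)}, "
                f"binder has {len(state.structure.binder)} residues"
            )
        threaded = state.structure.copy()
        threaded.binder.residue_names = [ONE_TO_THREE.get(a, "UNK") for a in seq]
        relaxed = relaxer(threaded)
        if [c.chain_id for c in relaxed.chains] != [c.chain_id for c in threaded.chains] or any(
            len(relaxed.chain(c.chain_id)) != len(c) for c in threaded.chains
        ):
            raise ValueError("relaxer altered the chain topology")
        for tid, names in target_names.items():
            if list(relaxed.chain(tid).residue_names) != names:
                raise ValueError(f"target chain {tid!r} sequence was modified")
        state.structure = relaxed
        state.binder_sequence = seq
        state.iteration = it
        state.log.append(
            {"iteration": it, "sequence": seq, "structure_id": _structure_digest(relaxed)}
        )
    return state


_AA1 = "ACDEFGHIKLMNPQRSTVWY"


class MockDesigner:
    """Deterministic stand-in for an inverse-folding designer: emits a seeded
    random binder sequence of the correct length on every call."""

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)

    def __call__(self, masked: ComplexStructure) -> str:
        n = len(masked.binder)
        return "".join(_AA1[k] for k in self._rng.integers(0, len(_AA1), size=n))


class MockRelaxer:
    """Deterministic stand-in for structural relaxation: applies a small
    seeded coordinate jitter to every chain, preserving topology."""

    def __init__(self, seed: int = 0, scale: float = 0.05):
        self._rng = np.random.default_rng(seed)
        self.scale = scale

    def __call__(self, cs: ComplexStructure) -> ComplexStructure:
        out = cs.copy()
        for chain in out.chains:
            chain.ca_coords = chain.ca_coords + self._rng.normal(
                0.0, self.scale, size=chain.ca_coords.shape
            )
        return out


# ---------------------------------------------------------------------------
# Campaign
# ---------------------------------------------------------------------------

@dataclass
class CampaignResult:
    records: list[DesignRecord]
    verdicts: list[FilterVerdict]
    report_rows: list[tuple[str, float]]
    n_errors: int = 0

    @property
    def pass_ids(self) -> set[str]:
        return {v.design_id for v in self.verdicts if v.passed}


def _load_designs_from_files(inputs: Mapping) -> tuple[list[DesignRecord], int]:
    predicted_dir = Path(inputs["predicted_dir"])
    confidence_dir = Path(inputs.get("confidence_dir", predicted_dir))
    binder_chain = inputs.get("binder_chain", "A")
    target_chains = list(inputs.get("target_chains", ["B"]))
    designed_path = inputs.get("designed")
    labels: dict[str, bool] = {}
    if inputs.get("labels"):
        for line in Path(inputs["labels"]).read_text().splitlines()[1:]:
            did, lab = line.split("\t")
            labels[did] = lab.strip() in ("True", "true", "1")

    shared_designed: ComplexStructure | None = None
    if designed_path and Path(designed_path).is_file():
        shared_designed = read_structure(
            Path(designed_path).read_text(), binder_chain, target_chains
        )

    pdbs = sorted(predicted_dir.glob("*.pdb"))
    if not pdbs:
        raise ValueError(f"no designs found in {predicted_dir}")
    records: list[DesignRecord] = []
    n_errors = 0
    for pdb_path in pdbs:
        design_id = pdb_path.stem
        mets: dict[str, float] = {}
        try:
            predicted = read_structure(pdb_path.read_text(), binder_chain, target_chains)
        except Exception as exc:
            logger.error("failed to parse %s: %s", pdb_path.name, exc)
            n_errors += 1
            continue
        conf_path = confidence_dir / f"{design_id}.json"
        if conf_path.exists():
            try:
                bundle = read_confidence(
                    conf_path.read_text(), predicted.residue_chain_labels()
                )
                mets["pae_interaction"] = metrics.pae_interaction(bundle, binder_chain)
                mets["binder_plddt"] = metrics.binder_plddt(bundle, binder_chain)
            except Exception as exc:
                logger.error("failed to parse %s: %s", conf_path.name, exc)
                n_errors += 1
        else:
            logger.warning("design %s has no confidence file; metrics absent", design_id)
        designed = shared_designed
        if designed is None and designed_path:
            per_path = Path(designed_path) / f"{design_id}.pdb"
            if per_path.exists():
                designed = read_structure(per_path.read_text(), binder_chain, target_chains)
        if designed is not None:
            mets["monomer_rmsd"] = metrics.monomer_ca_rmsd(predicted.binder, designed.binder)
            mets["af2_complex_rmsd"] = metrics.complex_aligned_rmsd(
                predicted, designed, "all_residues"
            )
        records.append(
            DesignRecord(
                design_id=design_id,
                target_name=str(inputs.get("target_name", "")),
                metrics=mets,
                label=labels.get(design_id),
            )
        )
    return records, n_errors


def run_campaign(config: Mapping) -> CampaignResult:
    """Score -> filter -> evaluate, from a synth spec or from input files.

    Config keys: one of ``synth`` (BenchmarkSpec fields) or ``inputs``
    (``predicted_dir``, optional ``designed`` file-or-dir, optional
    ``confidence_dir``, ``binder_chain``, ``target_chains``, optional
    ``labels`` TSV); optional ``filter`` criteria mapping (defaults to the
    standard two-metric screen); optional ``evaluate`` options (``metric``,
    ``direction``, ``fraction``); optional ``output_dir``.

    The run is idempotent: identical inputs produce byte-identical output
    files.  Designs whose files fail to parse are logged and skipped and
    counted in ``n_errors``.
    """
    n_errors = 0
    if ("synth" in config) == ("inputs" in config):
        raise ValueError("config must provide exactly one of 'synth' or 'inputs'")
    if "synth" in config:
        spec = synth.BenchmarkSpec(**config["synth"])
        records = synth.make_benchmark(spec)
    else:
        records, n_errors = _load_designs_from_files(config["inputs"])
        if not records:
            raise ValueError("no designs found")

    filt_cfg = config.get("filter")
    criteria = (
        FilterCriteria.default() if not filt_cfg else FilterCriteria.from_mapping(filt_cfg)
    )
    verdicts = apply_filter(records, criteria)
    n_pass = sum(v.passed for v in verdicts)

    report_rows: list[tuple[str, float]] = [
        ("n_total", float(len(records))),
        ("n_pass", float(n_pass)),
        ("pass_rate", n_pass / len(records)),
    ]
    eval_cfg = dict(config.get("evaluate") or {})
    labelled = all(rec.label is not None for rec in records)
    if labelled and eval_cfg:
        metric = eval_cfg.get("metric", "pae_interaction")
        direction = eval_cfg.get("direction", "min")
        fraction = float(eval_cfg.get("fraction", 0.01))
        report_rows.append(
            (
                f"success_rate_top_{fraction:g}",
                evalx.success_rate_top_fraction(records, metric, fraction, direction),
            )
        )
        report_rows.append(
            (f"auc_{metric}", evalx.roc_curve(records, metric, direction).auc)
        )

    result = CampaignResult(
        records=records, verdicts=verdicts, report_rows=report_rows, n_errors=n_errors
    )

    if config.get("output_dir"):
        outdir = Path(config["output_dir"])
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "scores.tsv").write_text(write_score_table(records))
        vlines = ["design_id\tpass\tfailed_criteria\tmissing_metrics"]
        for v in verdicts:
            vlines.append(
                f"{v.design_id}\t{v.passed}\t"
                f"{','.join(v.failed_criteria)}\t{','.join(v.missing_metrics)}"
            )
        (outdir / "verdicts.tsv").write_text("\n".join(vlines) + "\n")
        (outdir / "report.tsv").write_text(evalx.format_report(report_rows))
    return result
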