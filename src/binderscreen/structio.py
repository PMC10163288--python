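"""Core structure, confidence and score-table types with their on-disk formats.

The package works on minimal representations of designed binder/target
complexes: only C-alpha coordinates are kept, because every downstream
accuracy metric is a C-alpha quantity.  Structures travel as plain PDB
ATOM records, model-confidence output (per-residue pLDDT and the pairwise
predicted-aligned-error matrix) as JSON, and per-design score tables as
tab-separated text.

Residue order convention: wherever a flat per-residue indexing is needed
(confidence matrices, prediction payloads) the binder chain comes first,
followed by the target chains in their declared order, 0-based.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChainStructure",
    "ComplexStructure",
    "ConfidenceBundle",
    "DesignRecord",
    "read_structure",
    "write_structure",
    "read_confidence",
    "write_confidence",
    "read_score_table",
    "write_score_table",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

# 20 canonical amino acids; enough for designed minibinders.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class ChainStructure:
    """One chain's C-alpha trace.

    Parameters
    ----------
    chain_id : str
        Single-character chain label.
    residue_numbers : array-like of int
        Author residue numbers, strictly increasing.
    residue_names : sequence of str
        Three-letter residue codes, aligned with ``residue_numbers``.
    ca_coords : (n, 3) array-like of float
        C-alpha coordinates in Angstrom.
    """

    chain_id: str
    residue_numbers: np.ndarray
    residue_names: list[str]
    ca_coords: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_names = list(self.residue_names)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if len(self.chain_id) != 1:
            raise ValueError(f"chain_id must be a single character, got {self.chain_id!r}")
        n = len(self.residue_numbers)
        if len(self.residue_names) != n or self.ca_coords.shape != (n, 3):
            raise ValueError(
                f"chain {self.chain_id}: inconsistent lengths "
                f"(numbers={n}, names={len(self.residue_names)}, coords={self.ca_coords.shape})"
            )
        if n and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError(f"chain {self.chain_id}: residue numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residue_numbers)

    @property
    def sequence(self) -> str:
        """One-letter sequence; unknown residue codes become 'X'."""
        return "".join(THREE_TO_ONE.get(name, "X") for name in self.residue_names)

    def copy(self) -> "ChainStructure":
        return ChainStructure(
            self.chain_id,
            self.residue_numbers.copy(),
            list(self.residue_names),
            self.ca_coords.copy(),
        )


@dataclass
class ComplexStructure:
    """A binder/target complex: one binder chain plus one or more target chains."""

    chains: list[ChainStructure]
    binder_chain_id: str
    target_chain_ids: list[str]

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate chain ids: {ids}")
        if ids.count(self.binder_chain_id) != 1:
            raise ValueError(f"binder chain {self.binder_chain_id!r} not present exactly once")
        if not self.target_chain_ids:
            raise ValueError("target_chain_ids must be non-empty")
        if self.binder_chain_id in self.target_chain_ids:
            raise ValueError("binder chain cannot also be a target chain")
        for tid in self.target_chain_ids:
            if tid not in ids:
                raise ValueError(f"target chain {tid!r} not present in structure")

    def chain(self, chain_id: str) -> ChainStructure:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def binder(self) -> ChainStructure:
        return self.chain(self.binder_chain_id)

    @property
    def targets(self) -> list[ChainStructure]:
        return [self.chain(t) for t in self.target_chain_ids]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residue_chain_labels(self) -> list[str]:
        """Per-residue chain labels, binder first then targets in declared order."""
        labels: list[str] = []
        for c in [self.binder, *self.targets]:
            labels.extend([c.chain_id] * len(c))
        return labels

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            [c.copy() for c in self.chains],
            self.binder_chain_id,
            list(self.target_chain_ids),
        )


@dataclass
class ConfidenceBundle:
    """Per-residue pLDDT and the pairwise predicted-aligned-error matrix.

    ``pae[i, j]`` is the expected positional error (Angstrom) of residue j
    when the prediction is aligned on residue i's frame; the matrix is
    generally asymmetric.  ``chain_map`` assigns each matrix index to a
    chain label, in the same order as ``plddt``.
    """

    plddt: np.ndarray
    pae: np.ndarray
    chain_map: list[str]

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.pae = np.asarray(self.pae, dtype=float)
        self.chain_map = list(self.chain_map)
        n = len(self.plddt)
        if self.pae.ndim != 2 or self.pae.shape[0] != self.pae.shape[1]:
            raise ValueError(f"pae matrix must be square, got shape {self.pae.shape}")
        if self.pae.shape[0] != n or len(self.chain_map) != n:
            raise ValueError(
                f"size mismatch: plddt={n}, pae side={self.pae.shape[0]}, "
                f"chain_map={len(self.chain_map)}"
            )
        if n and (self.plddt.max() <= 1.0) and (self.plddt.min() >= 0.0):
            logger.warning("pLDDT values look like fractions in [0,1]; rescaling to 0-100")
            self.plddt = self.plddt * 100.0
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("pLDDT values must lie in [0, 100]")
        if np.any(self.pae < 0):
            raise ValueError("pae entries must be non-negative")

    @property
    def n_residues(self) -> int:
        return len(self.plddt)

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return np.array([c == chain_id for c in self.chain_map], dtype=bool)


@dataclass
class DesignRecord:
    """One design's identity, metric values and (optionally) its experimental label."""

    design_id: str
    target_name: str = ""
    metrics: dict[str, float] = field(default_factory=dict)
    label: bool | None = None

    def with_metrics(self, **extra: float) -> "DesignRecord":
        merged = dict(self.metrics)
        merged.update(extra)
        return replace(self, metrics=merged)


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def read_structure(
    pdb_text: str,
    binder_chain: str,
    target_chains: Sequence[str],
) -> ComplexStructure:
    """Parse PDB ATOM records into a C-alpha-only :class:`ComplexStructure`.

    Only the requested chains are retained.  Alternate locations resolve to
    the first-listed atom; insertion codes are rejected outright since
    designed models never carry them.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]
    present = {ch.name: ch for ch in model}
    wanted = [binder_chain, *target_chains]
    chains: list[ChainStructure] = []
    for chain_id in wanted:
        if chain_id not in present:
            raise ValueError(f"chain {chain_id!r} not found in PDB input")
        numbers: list[int] = []
        names: list[str] = []
        coords: list[tuple[float, float, float]] = []
        for res in present[chain_id]:
            icode = res.seqid.icode.strip()
            if icode:
                raise ValueError(
                    f"insertion code {icode!r} at {chain_id}{res.seqid.num}: not supported"
                )
            ca = None
            for atom in res:
                if atom.name == "CA":
                    ca = atom  # first-listed altloc wins
                    break
            if ca is None:
                raise ValueError(
                    f"residue {res.name} {chain_id}{res.seqid.num} lacks a CA atom"
                )
            numbers.append(res.seqid.num)
            names.append(res.name)
            coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        chains.append(ChainStructure(chain_id, numbers, names, coords))
    return ComplexStructure(chains, binder_chain, list(target_chains))


def write_structure(complex_structure: ComplexStructure) -> str:
    """Serialize a C-alpha-only complex to PDB ATOM records."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for chain in complex_structure.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for num, name, xyz in zip(chain.residue_numbers, chain.residue_names, chain.ca_coords):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(int(num), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, xyz))
            res.add_atom(atom)
            gchain.add_residue(res)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))


# ---------------------------------------------------------------------------
# Confidence bundles (JSON)
# ---------------------------------------------------------------------------

def read_confidence(json_text: str, chain_map: Sequence[str]) -> ConfidenceBundle:
    """Parse a ``{"plddt": [...], "pae": [[...]]}`` payload and validate sizes."""
    payload = json.loads(json_text)
    for key in ("plddt", "pae"):
        if key not in payload:
            raise ValueError(f"confidence payload missing {key!r}")
    plddt = np.asarray(payload["plddt"], dtype=float)
    pae = np.asarray(payload["pae"], dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError(f"pae matrix must be square, got shape {pae.shape}")
    if pae.shape[0] != len(chain_map):
        raise ValueError(
            f"pae side {pae.shape[0]} does not match chain map length {len(chain_map)}"
        )
    return ConfidenceBundle(plddt, pae, list(chain_map))


def write_confidence(bundle: ConfidenceBundle) -> str:
    payload = {
        "plddt": [float(x) for x in bundle.plddt],
        "pae": [[float(x) for x in row] for row in bundle.pae],
    }
    return json.dumps(payload)


# ---------------------------------------------------------------------------
# Score tables (TSV)
# ---------------------------------------------------------------------------

_RESERVED_COLUMNS = ("design_id", "target_name", "label")


def read_score_table(tsv_text: str) -> list[DesignRecord]:
    """Read a tab-separated score table into design records.

    The header must contain ``design_id``; ``target_name`` and boolean
    ``label`` columns are recognised, every other column is a numeric
    metric.  Empty cells become absent metrics, never zeros.
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str, keep_default_na=False)
    if "design_id" not in df.columns:
        raise ValueError("score table lacks a design_id column")
    ids = df["design_id"].tolist()
    dupes = {d for d in ids if ids.count(d) > 1}
    if dupes:
        raise ValueError(f"duplicate design_id values: {sorted(dupes)}")
    metric_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    records: list[DesignRecord] = []
    for _, row in df.iterrows():
        metrics: dict[str, float] = {}
        for col in metric_cols:
            cell = row[col].strip()
            if cell == "":
                continue
            try:
                metrics[col] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {cell!r} in column {col!r} "
                    f"for design {row['design_id']!r}"
                ) from None
        label: bool | None = None
        if "label" in df.columns:
            cell = row["label"].strip()
            if cell != "":
                if cell not in ("True", "False", "true", "false", "0", "1"):
                    raise ValueError(f"label cell {cell!r} is not boolean")
                label = cell in ("True", "true", "1")
        records.append(
            DesignRecord(
                design_id=row["design_id"],
                target_name=row.get("target_name", ""),
                metrics=metrics,
                label=label,
            )
        )
    return records


def write_score_table(records: Iterable[DesignRecord]) -> str:
    """Serialize records to TSV; metric values at 6 significant digits."""
    records = list(records)
    # stable metric-column order: first appearance across records
    metric_cols: list[str] = []
    for rec in records:
        for name in rec.metrics:
            if name not in metric_cols:
                metric_cols.append(name)
    has_target = any(rec.target_name for rec in records)
    has_label = any(rec.label is not None for rec in records)
    cols = ["design_id"]
    if has_target:
        cols.append("target_name")
    cols += metric_cols
    if has_label:
        cols.append("label")
    lines = ["\t".join(cols)]
    for rec in records:
        row = [rec.design_id]
        if has_target:
            row.append(rec.target_name)
        for name in metric_cols:
            if name in rec.metrics:
                row.append(f"{rec.metrics[name]:.6g}")
            else:
                row.append("")
        if has_label:
            row.append("" if rec.label is None else str(rec.label))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
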