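"""Superposition and the structure/confidence metrics used to screen designs.

Four quantities drive the screen:

* ``monomer_ca_rmsd`` — C-alpha RMSD of the predicted binder monomer to the
  designed monomer after optimal superposition; large values flag sequences
  that do not fold to the designed structure (type-I failures).
* ``complex_aligned_rmsd`` — C-alpha RMSD of the predicted complex to the
  designed complex after superposing on the *target* chains only, so the
  number measures whether the binder lands in the designed pose rather than
  how well either partner superposes on itself (type-II failures).
* ``binder_plddt`` — mean predicted-lDDT confidence over binder residues.
* ``pae_interaction`` — mean predicted aligned error over interchain
  binder/target residue pairs, the single most discriminative filter metric.

All superpositions are proper rigid transforms (reflections excluded),
solved in closed form by the Kabsch SVD construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import ChainStructure, ComplexStructure, ConfidenceBundle

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "monomer_ca_rmsd",
    "complex_aligned_rmsd",
    "binder_plddt",
    "pae_interaction",
]


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform ``x -> rotation @ x + translation`` plus the
    RMSD it achieves over the fitted atom set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def _as_points(coords: np.ndarray, name: str) -> np.ndarray:
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {pts.shape}")
    return pts


def kabsch_superpose(moving: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares superposition of ``moving`` onto ``reference``.

    Returns the proper rotation + translation minimising the RMSD between
    paired points; the mirror solution is rejected by flipping the sign of
    the smallest singular value when the raw SVD rotation is improper.
    """
    P = _as_points(moving, "moving")
    Q = _as_points(reference, "reference")
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in size: {P.shape[0]} vs {Q.shape[0]}")
    if P.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    cm = P.mean(axis=0)
    cr = Q.mean(axis=0)
    H = (P - cm).T @ (Q - cr)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def monomer_ca_rmsd(predicted: ChainStructure, designed: ChainStructure) -> float:
    """C-alpha RMSD of a predicted monomer to its design after optimal fit.

    Residues are paired by order; designed and predicted sequences are
    identical by construction so no alignment is attempted.
    """
    if len(predicted) != len(designed):
        raise ValueError(
            f"residue count mismatch: predicted={len(predicted)}, designed={len(designed)}"
        )
    return kabsch_superpose(predicted.ca_coords, designed.ca_coords).rmsd


def _stacked_coords(cs: ComplexStructure, chain_ids: list[str]) -> np.ndarray:
    return np.vstack([cs.chain(cid).ca_coords for cid in chain_ids])


def complex_aligned_rmsd(
    predicted: ComplexStructure,
    designed: ComplexStructure,
    scope: str = "all_residues",
) -> float:
    """C-alpha RMSD of a predicted complex to the designed complex.

    The superposition is computed on target-chain C-alphas only and then
    applied without refitting; the RMSD is evaluated over ``scope``:
    ``"binder_only"`` (binder accuracy relative to the target frame) or
    ``"all_residues"``.
    """
    if scope not in ("binder_only", "all_residues"):
        raise ValueError(f"unknown scope {scope!r}")
    if predicted.binder_chain_id != designed.binder_chain_id:
        raise ValueError("binder chain labels differ between predicted and designed")
    for cid in [designed.binder_chain_id, *designed.target_chain_ids]:
        try:
            pc, dc = predicted.chain(cid), designed.chain(cid)
        except KeyError:
            raise ValueError(f"chain {cid!r} missing from predicted structure") from None
        if len(pc) != len(dc):
            raise ValueError(f"chain {cid!r}: residue counts differ ({len(pc)} vs {len(dc)})")
    fit = kabsch_superpose(
        _stacked_coords(predicted, designed.target_chain_ids),
        _stacked_coords(designed, designed.target_chain_ids),
    )
    if scope == "binder_only":
        eval_ids = [designed.binder_chain_id]
    else:
        eval_ids = [designed.binder_chain_id, *designed.target_chain_ids]
    moved = fit.apply(_stacked_coords(predicted, eval_ids))
    ref = _stacked_coords(designed, eval_ids)
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


def binder_plddt(bundle: ConfidenceBundle, binder_chain: str) -> float:
    """Mean per-residue pLDDT over binder residues (0-100 scale)."""
    mask = bundle.chain_mask(binder_chain)
    if not mask.any():
        raise ValueError(f"no residues assigned to binder chain {binder_chain!r}")
    return float(bundle.plddt[mask].mean())


def pae_interaction(bundle: ConfidenceBundle, binder_chain: str) -> float:
    """Mean predicted aligned error over interchain binder/target pairs.

    Computed as the average of the two off-diagonal block means —
    ``pae[binder, target]`` and ``pae[target, binder]`` — which makes the
    result invariant to transposing the matrix and, with equal block sizes,
    identical to the grand mean over all ordered interchain pairs.
    Intrachain entries and the diagonal never contribute.
    """
    mask = bundle.chain_mask(binder_chain)
    if not mask.any():
        raise ValueError(f"no residues assigned to binder chain {binder_chain!r}")
    if mask.all():
        raise ValueError("bundle has no target residues: no interchain pairs")
    bt = bundle.pae[np.ix_(mask, ~mask)]
    tb = bundle.pae[np.ix_(~mask, mask)]
    return float((bt.mean() + tb.mean()) / 2.0)
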