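"""Superposition and screening metrics against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from binderscreen import synth
from binderscreen.metrics import (
    binder_plddt,
    complex_aligned_rmsd,
    kabsch_superpose,
    monomer_ca_rmsd,
    pae_interaction,
)
from binderscreen.structio import ConfidenceBundle

from conftest import random_bundle, simple_chain


def rmsd_after_rotvec(rotvec, P, Q):
    """RMSD of centred P rotated by rotvec against centred Q."""
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    R = Rotation.from_rotvec(rotvec).as_matrix()
    return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))


def numeric_best_rmsd(P, Q):
    """Numerical-optimization oracle: minimise RMSD over rotation vectors
    from many starting points."""
    best = np.inf
    for x0 in [np.zeros(3), [3, 0, 0], [0, 3, 0], [0, 0, 3], [1.5, 1.5, 1.5]]:
        res = minimize(rmsd_after_rotvec, x0, args=(P, Q), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identity(self, rng):
        P = rng.normal(size=(10, 3))
        sp = kabsch_superpose(P, P)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sp.rotation, np.eye(3), atol=1e-12)

    def test_rigid_motion_recovered(self, rng):
        P = rng.normal(size=(12, 3))
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ R90.T + np.array([1.0, 2.0, 3.0])
        sp = kabsch_superpose(P, Q)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sp.apply(P), Q, atol=1e-10)

    def test_rotation_always_proper(self, rng):
        # near-planar sets tempt the mirror solution
        for _ in range(20):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            Q[:, 2] *= 0.01
            sp = kabsch_superpose(P, Q)
            assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_numeric_oracle(self, rng):
        for _ in range(10):
            n = rng.integers(6, 30)
            P = rng.normal(size=(n, 3))
            Q = rng.normal(size=(n, 3))
            sp = kabsch_superpose(P, Q)
            assert sp.rmsd == pytest.approx(numeric_best_rmsd(P, Q), abs=1e-6)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="size"):
            kabsch_superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="3 points"):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestMonomerRmsd:
    def test_self_is_zero_and_symmetric(self, rng):
        a = simple_chain("A", rng.normal(size=(25, 3)))
        b = simple_chain("A", a.ca_coords + rng.normal(0, 0.5, size=(25, 3)))
        assert monomer_ca_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)
        assert monomer_ca_rmsd(a, b) == pytest.approx(monomer_ca_rmsd(b, a), abs=1e-12)

    def test_rigid_transform_is_zero(self, rng):
        a = simple_chain("A", rng.normal(size=(20, 3)))
        R = Rotation.from_rotvec([0.3, -0.8, 0.5]).as_matrix()
        b = simple_chain("A", a.ca_coords @ R.T + [4.0, -2.0, 7.0])
        assert monomer_ca_rmsd(b, a) == pytest.approx(0.0, abs=1e-10)

    def test_single_displaced_residue_bounded_by_unfitted_rmsd(self, rng):
        coords = rng.normal(size=(25, 3)) * 5
        moved = coords.copy()
        moved[7] += np.array([2.0, 0.0, 0.0])
        a, b = simple_chain("A", coords), simple_chain("A", moved)
        val = monomer_ca_rmsd(b, a)
        # superposition can only reduce the direct 2.0/sqrt(25) RMSD
        assert val <= 2.0 / np.sqrt(25) + 1e-12
        assert val == pytest.approx(numeric_best_rmsd(moved, coords), abs=1e-6)

    def test_length_mismatch(self, rng):
        a = simple_chain("A", rng.normal(size=(5, 3)))
        b = simple_chain("A", rng.normal(size=(6, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            monomer_ca_rmsd(a, b)


class TestComplexAlignedRmsd:
    def test_identical_is_zero(self, toy_complex):
        for scope in ("binder_only", "all_residues"):
            assert complex_aligned_rmsd(toy_complex, toy_complex, scope) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_pure_binder_translation_is_exact(self, toy_complex):
        moved = toy_complex.copy()
        moved.binder.ca_coords = moved.binder.ca_coords + np.array([0.0, 3.0, 0.0])
        assert complex_aligned_rmsd(moved, toy_complex, "binder_only") == pytest.approx(
            3.0, abs=1e-12
        )

    def test_common_rigid_motion_invariance(self, toy_complex, rng):
        moved = synth.perturb_structure(toy_complex, 1.5, "binder_only", seed=5)
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        t = rng.normal(size=3) * 10
        a, b = moved.copy(), toy_complex.copy()
        for cs in (a, b):
            for chain in cs.chains:
                chain.ca_coords = chain.ca_coords @ R.T + t
        assert complex_aligned_rmsd(a, b, "binder_only") == pytest.approx(
            complex_aligned_rmsd(moved, toy_complex, "binder_only"), abs=1e-9
        )

    def test_all_residue_value_matches_direct_formula(self, toy_complex, rng):
        pred = toy_complex.copy()
        for chain in pred.chains:
            chain.ca_coords = chain.ca_coords + rng.normal(0, 0.3, chain.ca_coords.shape)
        got = complex_aligned_rmsd(pred, toy_complex, "all_residues")
        # independent oracle: scipy aligns the target chains, then the
        # direct RMSD formula over all residues without refitting
        Pt, Qt = pred.chain("B").ca_coords, toy_complex.chain("B").ca_coords
        rot, _ = Rotation.align_vectors(Qt - Qt.mean(0), Pt - Pt.mean(0))
        P_all = np.vstack([pred.chain("A").ca_coords, Pt])
        Q_all = np.vstack([toy_complex.chain("A").ca_coords, Qt])
        moved = (P_all - Pt.mean(0)) @ rot.as_matrix().T + Qt.mean(0)
        expected = np.sqrt(np.mean(np.sum((moved - Q_all) ** 2, axis=1)))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_missing_chain_error(self, toy_complex):
        binder_only = synth.make_toy_complex(10, 20, seed=1, target_chain="C")
        with pytest.raises(ValueError, match="'B'"):
            complex_aligned_rmsd(binder_only, toy_complex)


class TestConfidenceMetrics:
    def test_binder_plddt_ignores_target(self):
        bundle = ConfidenceBundle([80.0, 100.0, 10.0, 10.0], np.ones((4, 4)), ["A", "A", "B", "B"])
        assert binder_plddt(bundle, "A") == pytest.approx(90.0)

    def test_binder_plddt_matches_loop_oracle(self, rng):
        bundle = random_bundle(rng, 7, 13)
        expected = sum(
            p for p, c in zip(bundle.plddt, bundle.chain_map) if c == "A"
        ) / 7
        assert binder_plddt(bundle, "A") == pytest.approx(expected, abs=1e-12)

    def test_constant_matrix(self):
        bundle = ConfidenceBundle([90.0] * 4, np.full((4, 4), 7.0), ["A", "A", "B", "B"])
        assert pae_interaction(bundle, "A") == pytest.approx(7.0)

    def test_two_by_two_block_enumeration(self):
        pae = np.zeros((4, 4))
        pae[0:2, 2:4] = [[4.0, 6.0], [8.0, 10.0]]
        pae[2:4, 0:2] = 2.0
        bundle = ConfidenceBundle([90.0] * 4, pae, ["A", "A", "B", "B"])
        # block means 7.0 and 2.0 -> 4.5; equals grand mean 36/8 over all
        # 8 ordered interchain entries
        assert pae_interaction(bundle, "A") == pytest.approx(4.5)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            nb, nt = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            bundle = random_bundle(rng, nb, nt)
            total = n = 0
            for i in range(nb + nt):
                for j in range(nb + nt):
                    if (bundle.chain_map[i] == "A") != (bundle.chain_map[j] == "A"):
                        total += bundle.pae[i, j]
                        n += 1
            # equal block cardinalities (nb*nt each way): grand mean applies
            assert pae_interaction(bundle, "A") == pytest.approx(total / n, abs=1e-12)

    def test_transpose_diagonal_and_intrachain_invariance(self, rng):
        bundle = random_bundle(rng, 5, 9)
        base = pae_interaction(bundle, "A")
        transposed = ConfidenceBundle(bundle.plddt, bundle.pae.T.copy(), bundle.chain_map)
        assert pae_interaction(transposed, "A") == pytest.approx(base, abs=1e-12)
        scrambled = bundle.pae.copy()
        scrambled[:5, :5] = rng.uniform(0, 30, (5, 5))
        scrambled[5:, 5:] = rng.uniform(0, 30, (9, 9))
        bundle2 = ConfidenceBundle(bundle.plddt, scrambled, bundle.chain_map)
        assert pae_interaction(bundle2, "A") == pytest.approx(base, abs=1e-12)

    def test_single_chain_bundle_rejected(self, rng):
        bundle = ConfidenceBundle(rng.uniform(50, 90, 5), rng.uniform(0, 30, (5, 5)), ["A"] * 5)
        with pytest.raises(ValueError, match="interchain"):
            pae_interaction(bundle, "A")
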