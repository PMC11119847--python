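"""Pose assembly, docking RMSD, and force-field relaxation."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

import qubodock as qd


@pytest.fixture(scope="module")
def planted_pose(chain_instance):
    q = chain_instance.qubo()
    sol = qd.Solution(
        chain_instance.planted,
        qd.evaluate(q, chain_instance.planted),
        True,
    )
    return qd.assemble(sol, chain_instance.placements, chain_instance.fragmentation)


def _ideal_benzene():
    """Benzene with exact D6h coordinates so a 60-degree rotation is an
    exact automorphism of the geometry."""
    mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1"))
    conf = Chem.Conformer(mol.GetNumAtoms())
    for k in range(6):
        ang = np.pi * k / 3.0
        conf.SetAtomPosition(k, Point3D(1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0))
        conf.SetAtomPosition(6 + k, Point3D(2.48 * np.cos(ang), 2.48 * np.sin(ang), 0.0))
    mol.AddConformer(conf)
    return mol


class TestAssemble:
    def test_chain_assembly_graph_and_bond_lengths(self, chain_instance, planted_pose):
        """The planted solution reassembles into the parent chain with all
        formed bonds inside the generator's bond window."""
        parent = chain_instance.compound
        assert Chem.MolToSmiles(Chem.RemoveHs(planted_pose.mol)) == parent.smiles
        frag = chain_instance.fragmentation
        # formed bonds sit at the attachment heavy atoms; check their lengths
        conf = planted_pose.mol.GetConformer()
        heavy = [a.GetIdx() for a in planted_pose.mol.GetAtoms() if a.GetAtomicNum() > 1]
        for bond in planted_pose.mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in heavy and j in heavy and not bond.IsInRing():
                d = np.linalg.norm(
                    np.array(conf.GetAtomPosition(i)) - np.array(conf.GetAtomPosition(j))
                )
                assert 1.2 <= d <= 2.0
        assert len(planted_pose.placement_ids) == frag.num_fragments

    def test_single_fragment_compound_passthrough(self):
        inst = qd.generate_instance(
            qd.GeneratorConfig(seed=2, n_fragments=1, placements_per_fragment=1)
        )
        q = inst.qubo()
        sol = qd.Solution(inst.planted, qd.evaluate(q, inst.planted), True)
        pose = qd.assemble(sol, inst.placements, inst.fragmentation)
        sel = inst.placements[0]
        np.testing.assert_allclose(pose.coordinates(), sel.coords, atol=1e-9)

    def test_invalid_solution_rejected(self, chain_instance):
        q = chain_instance.qubo()
        x = np.zeros(q.n, dtype=int)
        sol = qd.Solution(tuple(x), qd.evaluate(q, x), False)
        with pytest.raises(qd.ValidationError):
            qd.assemble(sol, chain_instance.placements, chain_instance.fragmentation)

    def test_no_cap_hydrogens_remain(self, chain_instance, planted_pose):
        parent = Chem.AddHs(chain_instance.compound.mol)
        assert planted_pose.mol.GetNumAtoms() == parent.GetNumAtoms()


class TestRMSD:
    def test_identity_is_zero(self, planted_pose):
        assert qd.compute_rmsd(planted_pose, planted_pose.mol).rmsd == pytest.approx(0.0)

    def test_uniform_translation(self, planted_pose):
        shifted = planted_pose.translated((1.0, 0.0, 0.0))
        report = qd.compute_rmsd(shifted, planted_pose.mol)
        assert report.rmsd == pytest.approx(1.0, abs=1e-9)

    def test_benzene_rotation_with_symmetry(self):
        ref = _ideal_benzene()
        rot = Chem.Mol(ref)
        conf = rot.GetConformer()
        c, s = np.cos(np.pi / 3), np.sin(np.pi / 3)
        for k in range(rot.GetNumAtoms()):
            p = conf.GetAtomPosition(k)
            conf.SetAtomPosition(k, Point3D(c * p.x - s * p.y, s * p.x + c * p.y, 0.0))
        assert qd.compute_rmsd(rot, ref, symmetry=True).rmsd == pytest.approx(0.0, abs=1e-9)
        assert qd.compute_rmsd(rot, ref, symmetry=False).rmsd > 1.0

    def test_symmetric_in_arguments(self, planted_pose):
        shifted = planted_pose.translated((0.4, -0.3, 0.2))
        a = qd.compute_rmsd(planted_pose, shifted.mol).rmsd
        b = qd.compute_rmsd(shifted, planted_pose.mol).rmsd
        assert a == pytest.approx(b)

    def test_graph_mismatch_rejected(self, planted_pose):
        other = Chem.AddHs(Chem.MolFromSmiles("CCCC"))
        AllChem.EmbedMolecule(other, randomSeed=1)
        with pytest.raises(qd.ValidationError):
            qd.compute_rmsd(planted_pose, other)


class TestMinimize:
    def test_relaxed_pose_is_near_fixed_point(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("CC"))
        AllChem.EmbedMolecule(mol, randomSeed=3)
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
        pose = qd.ReconstructedPose(mol)
        out = qd.minimize_pose(pose)
        assert qd.compute_rmsd(out, pose.mol).rmsd < 0.05

    def test_stretched_bond_shortens(self):
        """A 1.9 A C-C bond relaxes toward the UFF equilibrium length."""
        mol = Chem.AddHs(Chem.MolFromSmiles("CC"))
        AllChem.EmbedMolecule(mol, randomSeed=3)
        AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
        conf = mol.GetConformer()
        p0 = np.array(conf.GetAtomPosition(0))
        p1 = np.array(conf.GetAtomPosition(1))
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        stretch = 1.9 - np.linalg.norm(p1 - p0)
        # move atom 1 and its hydrogens outward along the bond axis
        for idx in [1] + [n.GetIdx() for n in mol.GetAtomWithIdx(1).GetNeighbors()
                          if n.GetAtomicNum() == 1]:
            p = np.array(conf.GetAtomPosition(idx)) + stretch * axis
            conf.SetAtomPosition(idx, Point3D(*p))
        d_before = np.linalg.norm(
            np.array(conf.GetAtomPosition(0)) - np.array(conf.GetAtomPosition(1))
        )
        assert d_before == pytest.approx(1.9, abs=1e-6)
        out = qd.minimize_pose(qd.ReconstructedPose(mol))
        oconf = out.mol.GetConformer()
        d_after = np.linalg.norm(
            np.array(oconf.GetAtomPosition(0)) - np.array(oconf.GetAtomPosition(1))
        )
        assert d_after < 1.7


def test_graph_fidelity_over_random_valid_solutions(chain_instance):
    """Every valid solution assembles to a molecule isomorphic to the
    parent compound (canonical SMILES equality on the heavy graph)."""
    q = chain_instance.qubo()
    pool = qd.postprocess_filter(
        qd.simulated_anneal(q, qd.SolverConfig(seed=5, restarts=60, sweeps=40)),
        q.groups,
    )
    assert len(pool) > 0
    parent_smiles = chain_instance.compound.smiles
    for sol in pool:
        pose = qd.assemble(sol, chain_instance.placements, chain_instance.fragmentation)
        assert Chem.MolToSmiles(Chem.RemoveHs(pose.mol)) == parent_smiles
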