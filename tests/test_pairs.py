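"""Pair energies, binarization rules, geometric mode, and the pre-filter."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

import qubodock as qd
from qubodock.pairs import UFFPairEnergies


@pytest.fixture(scope="module")
def chain2():
    """Embedded 2-fragment cyclopropane chain with its planted placements."""
    inst = qd.generate_instance(
        qd.GeneratorConfig(seed=3, mode="energy", n_fragments=2, placements_per_fragment=1)
    )
    p0 = inst.placements[inst.placements.groups[0][0]]
    p1 = inst.placements[inst.placements.groups[1][0]]
    return inst, p0, p1


def _translated(p, shift, index=99):
    return qd.Placement(index, p.fragment_id, p.coords + np.asarray(shift), p.score)


class TestENB:
    def test_distant_pair_is_exactly_zero(self, chain2):
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        far = _translated(p1, (50.0, 0, 0))
        assert calc.enb(p0, far) == 0.0

    def test_steric_overlap_exceeds_tolerance(self, chain2):
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        # drop fragment 1 onto fragment 0's centroid: heavy atoms overlap
        c0 = p0.centroid(inst.fragmentation)
        c1 = p1.centroid(inst.fragmentation)
        clashing = _translated(p1, c0 - c1)
        assert calc.enb(p0, clashing) > 500.0

    def test_vdw_contact_matches_independent_uff_evaluation(self, chain2):
        """ENB equals the dimer-minus-monomers UFF energy computed directly
        with rdkit, and is small and attractive at van-der-Waals contact."""
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        c0 = p0.centroid(inst.fragmentation)
        c1 = p1.centroid(inst.fragmentation)
        axis = (c1 - c0) / np.linalg.norm(c1 - c0)
        # centroid separation of 6 A puts the facing hydrogens near their
        # van-der-Waals minimum: weak attraction
        contact = _translated(p1, c0 + 6.0 * axis - c1)
        got = calc.enb(p0, contact)

        def raw_energy(mol, coords):
            m = Chem.Mol(mol)
            conf = Chem.Conformer(m.GetNumAtoms())
            for k, xyz in enumerate(coords):
                conf.SetAtomPosition(k, tuple(float(v) for v in xyz))
            m.RemoveAllConformers()
            m.AddConformer(conf)
            ff = AllChem.UFFGetMoleculeForceField(
                m, vdwThresh=10.0, ignoreInterfragInteractions=False
            )
            return ff.CalcEnergy()

        f0 = inst.fragmentation.fragments[0].mol
        f1 = inst.fragmentation.fragments[1].mol
        dimer = Chem.CombineMols(f0, f1)
        expected = (
            raw_energy(dimer, np.vstack([p0.coords, contact.coords]))
            - raw_energy(f0, p0.coords)
            - raw_energy(f1, contact.coords)
        )
        assert got == pytest.approx(expected, abs=1e-8)
        assert -5.0 < got < 0.0

    def test_same_fragment_pair_rejected(self, chain2):
        inst, p0, _ = chain2
        calc = UFFPairEnergies(inst.placements)
        with pytest.raises(qd.ValidationError):
            calc.enb(p0, _translated(p0, (1, 0, 0)))

    def test_symmetry(self, chain2):
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        assert calc.enb(p0, p1) == pytest.approx(calc.enb(p1, p0), rel=1e-9)
        assert calc.eb(p0, p1) == pytest.approx(calc.eb(p1, p0), rel=1e-9)

    def test_monotone_repulsion_below_contact(self, chain2):
        """Pushing two rigid fragments together along their centre line never
        decreases ENB between van-der-Waals contact and interpenetration
        (once atoms pass through each other the pair distances, and hence
        the energy, are no longer monotone in the centroid separation)."""
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        c0 = p0.centroid(inst.fragmentation)
        c1 = p1.centroid(inst.fragmentation)
        axis = (c1 - c0) / np.linalg.norm(c1 - c0)
        energies = []
        for sep in np.arange(5.5, 3.4, -0.25):
            target = c0 + axis * sep
            energies.append(calc.enb(p0, _translated(p1, target - c1)))
        assert all(b >= a - 1e-6 for a, b in zip(energies, energies[1:]))


class TestEB:
    def test_planted_chain_bond_is_accepted(self, chain2):
        """Consecutive planted placements form an undistorted bond."""
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        assert abs(calc.eb(p0, p1)) <= 500.0

    def test_stretched_bond_diverges(self, chain2):
        inst, p0, p1 = chain2
        calc = UFFPairEnergies(inst.placements)
        assert calc.eb(p0, _translated(p1, (6.0, 0, 0))) > 500.0

    def test_non_bonded_fragments_rejected(self):
        inst = qd.generate_instance(
            qd.GeneratorConfig(seed=3, mode="energy", n_fragments=3, placements_per_fragment=1)
        )
        calc = UFFPairEnergies(inst.placements)
        p0 = inst.placements[inst.placements.groups[0][0]]
        p2 = inst.placements[inst.placements.groups[2][0]]
        with pytest.raises(qd.ValidationError):
            calc.eb(p0, p2)


class TestBinarize:
    @pytest.mark.parametrize(
        "bonded, eb, enb, conn, clash",
        [
            # conn wins even when ENB is huge
            (True, -2.0, 900.0, -1, 0),
            # both thresholds exceeded: no bond, clash
            (True, 600.0, 700.0, 0, 1),
            # compatible non-bonded pair
            (False, None, -1.0, 0, 0),
            # non-bonded steric clash
            (False, None, 501.0, 0, 1),
            # boundary: EB exactly at tolerance still bonds
            (True, 500.0, 0.0, -1, 0),
            # boundary: ENB exactly at tolerance is not a clash
            (False, None, 500.0, 0, 0),
            (True, 501.0, 499.0, 0, 0),
        ],
    )
    def test_rules(self, bonded, eb, enb, conn, clash):
        pe = qd.PairEnergy(0, 1, enb, eb if bonded else None)
        (term,) = qd.binarize([pe], qd.EnergyTolerance(500.0))
        assert (term.conn, term.clash) == (conn, clash)
        assert term.clash * term.conn == 0

    def test_invalid_term_rejected(self):
        with pytest.raises(qd.ValidationError):
            qd.PairTerm(0, 1, 1, -1)


class TestGeometricMode:
    def test_attachment_inside_window_connects(self, chain_instance):
        frag = chain_instance.fragmentation
        p0 = chain_instance.placements[chain_instance.placements.groups[0][0]]
        p1 = chain_instance.placements[chain_instance.placements.groups[1][0]]
        term = qd.geometric_pair_term(frag, p0, p1)
        assert term.conn == -1 and term.clash == 0

    def test_close_approach_clashes(self, chain_instance):
        frag = chain_instance.fragmentation
        p0 = chain_instance.placements[chain_instance.placements.groups[0][0]]
        p2 = chain_instance.placements[chain_instance.placements.groups[2][0]]
        c0 = p0.centroid(frag)
        clashing = qd.Placement(99, 2, p2.coords + (c0 - p2.centroid(frag)), -1.0)
        term = qd.geometric_pair_term(frag, p0, clashing)
        assert term.clash == 1 and term.conn == 0

    def test_distant_pair_is_null(self, chain_instance):
        frag = chain_instance.fragmentation
        p0 = chain_instance.placements[chain_instance.placements.groups[0][0]]
        p2 = chain_instance.placements[chain_instance.placements.groups[2][0]]
        far = qd.Placement(99, 2, p2.coords + 50.0, -1.0)
        term = qd.geometric_pair_term(frag, p0, far)
        assert (term.clash, term.conn) == (0, 0)


class TestPrefilter:
    def test_far_pair_short_circuits(self, chain2):
        inst, p0, p1 = chain2
        far = _translated(p1, (15.0, 0, 0))
        term = qd.pair_prefilter(inst.fragmentation, p0, far, cutoff=8.0)
        assert term is not None and (term.clash, term.conn) == (0, 0)

    def test_near_pair_defers(self, chain2):
        inst, p0, p1 = chain2
        assert qd.pair_prefilter(inst.fragmentation, p0, p1, cutoff=8.0) is None

    def test_prefilter_never_disagrees_with_energy_path(self):
        """Soundness: on randomized placements the filtered and unfiltered
        term tables are identical."""
        inst = qd.generate_instance(
            qd.GeneratorConfig(
                seed=17, mode="energy", n_fragments=3, placements_per_fragment=3,
                decoy_displacement=6.0,
            )
        )
        with_f, _ = qd.compute_pair_terms(inst.placements, mode="energy")
        without_f, _ = qd.compute_pair_terms(
            inst.placements, mode="energy", prefilter_cutoff=None
        )
        assert with_f == without_f
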