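"""Turning a valid solution back into a docked compound pose.

Assembly concatenates the selected placements' coordinates, deletes the two
cap hydrogens at every inter-fragment bond, and adds the bond between the
attachment heavy atoms -- coordinates are not moved, so any distortion of the
formed bonds is left in place.  Cleanup of that distortion is delegated to an
optional force-field minimization with the protein held rigid.

Docking RMSD is computed in the shared protein frame (no superposition),
over heavy atoms, optionally minimized over graph automorphisms so that
topological symmetry (a CF3 rotor, a flipped phenyl ring) does not inflate
the value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .chem import Compound, FragmentationResult
from .errors import ParameterizationError, ValidationError
from .placements import PlacementSet
from .solvers import Solution


@dataclass
class ReconstructedPose:
    """A compound pose rebuilt from one placement per fragment."""

    mol: Chem.Mol
    placement_ids: dict[int, int] = field(default_factory=dict)
    solution_energy: float | None = None

    def coordinates(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def translated(self, shift) -> "ReconstructedPose":
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        s = np.asarray(shift, dtype=float)
        for i in range(mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, Point3D(p.x + s[0], p.y + s[1], p.z + s[2]))
        return ReconstructedPose(mol, dict(self.placement_ids), self.solution_energy)


@dataclass
class RMSDReport:
    rmsd: float
    mapping: tuple[int, ...]
    symmetry_corrected: bool


def assemble(
    solution: Solution,
    pset: PlacementSet,
    fragmentation: FragmentationResult,
) -> ReconstructedPose:
    """Merge the selected placements into one molecule.

    Requires a valid solution (exactly one placement per fragment).  The
    output molecule's heavy-atom graph is isomorphic to the parent
    compound's; cap hydrogens at formed bonds are removed, all other
    hydrogens are kept.
    """
    if not solution.valid:
        raise ValidationError("cannot assemble an invalid solution")
    chosen: dict[int, int] = {}
    for fid, members in pset.groups.items():
        sel = [i for i in members if solution.x[i] == 1]
        if len(sel) != 1:
            raise ValidationError(f"fragment {fid} has {len(sel)} selected placements")
        chosen[fid] = sel[0]

    rw = Chem.RWMol()
    offsets: dict[int, int] = {}
    coords: list[np.ndarray] = []
    for frag in fragmentation.fragments:
        offsets[frag.fragment_id] = rw.GetNumAtoms()
        placement = pset[chosen[frag.fragment_id]]
        sub = Chem.Mol(frag.mol)
        Chem.Kekulize(sub, clearAromaticFlags=True)
        amap = {}
        for atom in sub.GetAtoms():
            a = Chem.Atom(atom.GetAtomicNum())
            a.SetFormalCharge(atom.GetFormalCharge())
            a.SetNoImplicit(True)
            amap[atom.GetIdx()] = rw.AddAtom(a)
        for bond in sub.GetBonds():
            rw.AddBond(
                amap[bond.GetBeginAtomIdx()],
                amap[bond.GetEndAtomIdx()],
                bond.GetBondType(),
            )
        coords.append(np.asarray(placement.coords, dtype=float))
    all_coords = np.vstack(coords) if coords else np.zeros((0, 3))

    drop: list[int] = []
    for k1, k2 in fragmentation.bonds:
        rec1 = fragmentation.attachment_for_bond(k1, k2)
        rec2 = fragmentation.attachment_for_bond(k2, k1)
        rw.AddBond(
            offsets[k1] + rec1.heavy_atom,
            offsets[k2] + rec2.heavy_atom,
            Chem.BondType.SINGLE,
        )
        drop.extend([offsets[k1] + rec1.cap_hydrogen, offsets[k2] + rec2.cap_hydrogen])
    keep = [i for i in range(rw.GetNumAtoms()) if i not in set(drop)]
    for idx in sorted(drop, reverse=True):
        rw.RemoveAtom(idx)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for new_i, old_i in enumerate(keep):
        x, y, z = all_coords[old_i]
        conf.SetAtomPosition(new_i, Point3D(float(x), float(y), float(z)))
    mol.AddConformer(conf, assignId=True)
    return ReconstructedPose(
        mol=mol, placement_ids=chosen, solution_energy=solution.energy
    )


def _heavy_mol(mol: Chem.Mol) -> Chem.Mol:
    return Chem.RemoveHs(Chem.Mol(mol))


def compute_rmsd(
    pose: ReconstructedPose | Chem.Mol,
    reference: "Compound | Chem.Mol",
    symmetry: bool = True,
) -> RMSDReport:
    """Heavy-atom docking RMSD in the common frame, without superposition.

    With ``symmetry`` the RMSD is minimized over graph automorphisms of the
    shared molecular graph.  Raises :class:`ValidationError` if the two
    molecular graphs do not match.
    """
    probe = pose.mol if isinstance(pose, ReconstructedPose) else pose
    ref = reference.mol if isinstance(reference, Compound) else reference
    probe_h = _heavy_mol(probe)
    ref_h = _heavy_mol(ref)
    if probe_h.GetNumAtoms() != ref_h.GetNumAtoms():
        raise ValidationError("pose and reference have different heavy-atom counts")
    if ref_h.GetNumConformers() == 0 or probe_h.GetNumConformers() == 0:
        raise ValidationError("both molecules need 3D coordinates")
    p = np.asarray(probe_h.GetConformer().GetPositions(), dtype=float)
    r = np.asarray(ref_h.GetConformer().GetPositions(), dtype=float)
    matches = ref_h.GetSubstructMatches(
        probe_h, uniquify=False, useChirality=False, maxMatches=100000
    )
    if not matches:
        raise ValidationError("pose and reference molecular graphs do not match")
    if not symmetry:
        matches = matches[:1]
    best, best_map = np.inf, matches[0]
    for m in matches:
        d = p - r[list(m)]
        val = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        if val < best:
            best, best_map = val, m
    return RMSDReport(rmsd=best, mapping=tuple(best_map), symmetry_corrected=symmetry)


def minimize_pose(
    pose: ReconstructedPose,
    protein: Chem.Mol | None = None,
    force_field: str = "uff",
    max_iterations: int = 2000,
) -> ReconstructedPose:
    """Relax a reconstructed pose with a generic force field.

    With a protein (an RDKit molecule, e.g. from a PDB file) the compound is
    minimized inside the rigid protein: protein atoms are added as fixed
    points of the combined system.  Without one, only the compound's internal
    energy is minimized.  This is a generic substitute for the commercial
    minimization used in the reference workflow; numbers will differ.
    """
    if force_field != "uff":
        raise ValidationError(f"unsupported force field {force_field!r}")
    lig = Chem.Mol(pose.mol)
    n_lig = lig.GetNumAtoms()
    if protein is not None:
        system = Chem.CombineMols(lig, protein)
    else:
        system = lig
    system = Chem.Mol(system)
    if not AllChem.UFFHasAllMoleculeParams(system):
        raise ParameterizationError("UFF could not type the minimization system")
    ff = AllChem.UFFGetMoleculeForceField(
        system, ignoreInterfragInteractions=False
    )
    if ff is None:
        raise ParameterizationError("UFF force field construction failed")
    for idx in range(n_lig, system.GetNumAtoms()):
        ff.AddFixedPoint(idx)
    ff.Initialize()
    ff.Minimize(maxIts=max_iterations)
    conf = system.GetConformer()
    out = Chem.Mol(pose.mol)
    oconf = out.GetConformer()
    for i in range(n_lig):
        oconf.SetAtomPosition(i, conf.GetAtomPosition(i))
    return ReconstructedPose(out, dict(pose.placement_ids), pose.solution_energy)


def write_poses_sdf(
    poses: list[ReconstructedPose],
    path: str,
    reference: "Compound | None" = None,
) -> None:
    """Write reconstructed poses as SDF with energy/RMSD properties."""
    writer = Chem.SDWriter(path)
    try:
        for rank, pose in enumerate(poses):
            mol = Chem.Mol(pose.mol)
            mol.SetProp("_Name", f"pose_{rank}")
            mol.SetIntProp("rank", rank)
            if pose.solution_energy is not None:
                mol.SetDoubleProp("H", pose.solution_energy)
            if reference is not None:
                mol.SetDoubleProp("RMSD", compute_rmsd(pose, reference).rmsd)
            writer.write(mol)
    finally:
        writer.close()
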