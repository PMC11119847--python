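"""Pairwise placement relations: UFF energies and their binarization.

For every pair of placements of different fragments two interaction energies
are defined.  E_NB is the energy of the two capped fragments held at their
placed coordinates, treated as one system with no bond added, minus the
internal energy of each fragment alone at the same coordinates -- a pure
inter-fragment non-bonded energy that vanishes for distant pairs.  E_B, for
fragments that are covalently bonded in the parent compound, is the energy of
the merged molecule (the two cap hydrogens at the attachment removed, the
bond added) minus the same isolated-fragment energies; it contains the
distortion of the formed bond (stretch, angle, dihedral) plus all
intramolecular non-bonded terms.

Both are binarized against a single tolerance thE (default 500 kcal/mol):

    conn(i,j) = -1  if bonded and E_B <= thE, else 0
    clash(i,j) = 1  if conn(i,j) = 0 and E_NB > thE, else 0

A fast geometric mode replaces the force field with distance criteria, and a
pre-filter skips energy evaluation for pairs that are too distant to interact.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D
from scipy.spatial.distance import cdist

from .chem import AttachmentRecord, FragmentationResult
from .errors import ConfigurationError, ParameterizationError, ValidationError
from .placements import Placement, PlacementSet

DEFAULT_ENERGY_TOLERANCE = 500.0  # kcal/mol
DEFAULT_PREFILTER_CUTOFF = 8.0  # Angstrom
DEFAULT_CLASH_DISTANCE = 2.0  # Angstrom
DEFAULT_BOND_WINDOW = (1.2, 2.0)  # Angstrom
UFF_VDW_THRESH = 10.0  # Angstrom, RDKit UFF non-bonded cutoff


@dataclass(frozen=True)
class EnergyTolerance:
    """thE: pair energies above it mark a clash / an unformable bond."""

    thE: float = DEFAULT_ENERGY_TOLERANCE

    def __post_init__(self):
        if self.thE <= 0:
            raise ConfigurationError("energy tolerance thE must be positive")


@dataclass
class PairEnergy:
    """Raw interaction energies of a placement pair (kcal/mol).

    ``eb`` is None for pairs whose fragments are not bonded in the parent.
    """

    i: int
    j: int
    enb: float
    eb: float | None = None

    @property
    def bonded(self) -> bool:
        return self.eb is not None


@dataclass(frozen=True)
class PairTerm:
    """Binarized pair relation entering H2 (clash) and H3 (conn)."""

    i: int
    j: int
    clash: int
    conn: int

    def __post_init__(self):
        if self.clash not in (0, 1) or self.conn not in (-1, 0):
            raise ValidationError("clash must be 0/1 and conn must be -1/0")
        if self.clash * self.conn != 0:
            raise ValidationError("clash and conn are mutually exclusive")


def _set_conformer(mol: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    mol = Chem.Mol(mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for k, (x, y, z) in enumerate(np.asarray(coords, dtype=float)):
        conf.SetAtomPosition(k, Point3D(float(x), float(y), float(z)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf, assignId=True)
    return mol


def uff_energy(mol: Chem.Mol, coords: np.ndarray) -> float:
    """Single-point UFF energy (kcal/mol) of ``mol`` at ``coords``."""
    m = _set_conformer(mol, coords)
    if not AllChem.UFFHasAllMoleculeParams(m):
        bad = [
            f"{a.GetSymbol()}{a.GetIdx()}"
            for a in m.GetAtoms()
            # UFF covers most elements; report all atoms for diagnosis
        ]
        raise ParameterizationError(f"UFF could not type molecule with atoms {bad}")
    ff = AllChem.UFFGetMoleculeForceField(
        m, vdwThresh=UFF_VDW_THRESH, ignoreInterfragInteractions=False
    )
    if ff is None:
        raise ParameterizationError("UFF force field construction failed")
    return float(ff.CalcEnergy())


class UFFPairEnergies:
    """Computes and caches E_NB / E_B for the placements of one instance."""

    def __init__(self, pset: PlacementSet):
        self.pset = pset
        self.frag = pset.fragmentation
        self._single: dict[int, float] = {}
        self._combined: dict[tuple[int, int], Chem.Mol] = {}
        self._merged: dict[tuple[int, int], tuple[Chem.Mol, list[int]]] = {}

    def _single_energy(self, p: Placement) -> float:
        if p.index not in self._single:
            mol = self.frag.fragments[p.fragment_id].mol
            self._single[p.index] = uff_energy(mol, p.coords)
        return self._single[p.index]

    def _combined_template(self, fi: int, fj: int) -> Chem.Mol:
        key = (fi, fj)
        if key not in self._combined:
            mol = Chem.CombineMols(
                self.frag.fragments[fi].mol, self.frag.fragments[fj].mol
            )
            self._combined[key] = mol
        return self._combined[key]

    def _merged_template(self, fi: int, fj: int) -> tuple[Chem.Mol, list[int]]:
        """Merged molecule of bonded fragments fi--fj, plus the kept atom
        indices (into the concatenated [fi atoms, fj atoms] order)."""
        key = (fi, fj)
        if key not in self._merged:
            rec_i = self.frag.attachment_for_bond(fi, fj)
            rec_j = self.frag.attachment_for_bond(fj, fi)
            ni = self.frag.fragments[fi].num_atoms
            combined = Chem.RWMol(self._combined_template(fi, fj))
            drop = sorted([rec_i.cap_hydrogen, ni + rec_j.cap_hydrogen], reverse=True)
            combined.AddBond(
                rec_i.heavy_atom, ni + rec_j.heavy_atom, Chem.BondType.SINGLE
            )
            for idx in drop:
                combined.RemoveAtom(idx)
            mol = combined.GetMol()
            Chem.SanitizeMol(mol)
            keep = [k for k in range(ni + self.frag.fragments[fj].num_atoms)
                    if k not in drop]
            self._merged[key] = (mol, keep)
        return self._merged[key]

    def enb(self, pi: Placement, pj: Placement) -> float:
        """Inter-fragment non-bonded energy of a placement pair."""
        if pi.fragment_id == pj.fragment_id:
            raise ValidationError("E_NB is defined only across different fragments")
        mol = self._combined_template(pi.fragment_id, pj.fragment_id)
        coords = np.vstack([pi.coords, pj.coords])
        e_pair = uff_energy(mol, coords)
        return e_pair - self._single_energy(pi) - self._single_energy(pj)

    def eb(self, pi: Placement, pj: Placement) -> float:
        """Merged-molecule energy (bond formed) relative to the isolated
        capped fragments; includes bond/angle/dihedral distortion."""
        fi, fj = pi.fragment_id, pj.fragment_id
        if not self.frag.are_bonded(fi, fj):
            raise ValidationError(
                f"fragments {fi} and {fj} are not bonded in the parent compound"
            )
        mol, keep = self._merged_template(fi, fj)
        coords = np.vstack([pi.coords, pj.coords])[keep]
        e_merged = uff_energy(mol, coords)
        return e_merged - self._single_energy(pi) - self._single_energy(pj)


def compute_enb(pset: PlacementSet, pi: Placement, pj: Placement) -> float:
    return UFFPairEnergies(pset).enb(pi, pj)


def compute_eb(pset: PlacementSet, pi: Placement, pj: Placement) -> float:
    return UFFPairEnergies(pset).eb(pi, pj)


def binarize(
    pairs: list[PairEnergy], tol: EnergyTolerance | float = DEFAULT_ENERGY_TOLERANCE
) -> list[PairTerm]:
    """Apply the two threshold rules, conn first, then clash."""
    thE = tol.thE if isinstance(tol, EnergyTolerance) else float(tol)
    terms = []
    for pe in pairs:
        conn = -1 if (pe.bonded and pe.eb <= thE) else 0
        clash = 1 if (conn == 0 and pe.enb > thE) else 0
        terms.append(PairTerm(pe.i, pe.j, clash, conn))
    return terms


def _min_heavy_distance(
    frag: FragmentationResult, pi: Placement, pj: Placement
) -> float:
    a = pi.heavy_coords(frag)
    b = pj.heavy_coords(frag)
    return float(cdist(a, b).min())


def _attachment_distance(
    frag: FragmentationResult, pi: Placement, pj: Placement
) -> float:
    rec_i = frag.attachment_for_bond(pi.fragment_id, pj.fragment_id)
    rec_j = frag.attachment_for_bond(pj.fragment_id, pi.fragment_id)
    return float(
        np.linalg.norm(pi.coords[rec_i.heavy_atom] - pj.coords[rec_j.heavy_atom])
    )


def geometric_pair_term(
    frag: FragmentationResult,
    pi: Placement,
    pj: Placement,
    clash_distance: float = DEFAULT_CLASH_DISTANCE,
    bond_window: tuple[float, float] = DEFAULT_BOND_WINDOW,
) -> PairTerm:
    """Distance-based stand-in for the energy criteria.

    conn = -1 iff the fragments are bonded in the parent and the attachment
    heavy atoms lie inside ``bond_window``; clash = 1 iff the pair is not
    connected that way and any two heavy atoms come closer than
    ``clash_distance``.
    """
    if clash_distance <= 0 or bond_window[0] <= 0 or bond_window[1] <= bond_window[0]:
        raise ConfigurationError("geometric thresholds must be positive and ordered")
    i, j = pi.index, pj.index
    conn = 0
    if frag.are_bonded(pi.fragment_id, pj.fragment_id):
        d = _attachment_distance(frag, pi, pj)
        if bond_window[0] <= d <= bond_window[1]:
            conn = -1
    clash = 0
    if conn == 0 and _min_heavy_distance(frag, pi, pj) < clash_distance:
        clash = 1
    return PairTerm(i, j, clash, conn)


def pair_prefilter(
    frag: FragmentationResult,
    pi: Placement,
    pj: Placement,
    cutoff: float = DEFAULT_PREFILTER_CUTOFF,
) -> PairTerm | None:
    """Cheap geometric screen before any energy evaluation.

    Returns ``PairTerm(i, j, 0, 0)`` when the fragments are so far apart that
    neither a clash nor a bond is geometrically possible; returns None to
    defer to the energy path.
    """
    if cutoff <= 0:
        raise ConfigurationError("prefilter cutoff must be positive")
    if _min_heavy_distance(frag, pi, pj) > cutoff:
        return PairTerm(pi.index, pj.index, 0, 0)
    return None


def compute_pair_terms(
    pset: PlacementSet,
    mode: str = "energy",
    tol: float = DEFAULT_ENERGY_TOLERANCE,
    prefilter_cutoff: float | None = DEFAULT_PREFILTER_CUTOFF,
    clash_distance: float = DEFAULT_CLASH_DISTANCE,
    bond_window: tuple[float, float] = DEFAULT_BOND_WINDOW,
) -> tuple[list[PairTerm], pd.DataFrame]:
    """Pair terms for all cross-fragment placement pairs of an instance.

    Returns the term list and a table (i, j, ENB, EB, clash, conn); energies
    are NaN in geometric mode or when the pre-filter short-circuited a pair.
    Pairs of placements of the same fragment are excluded (multiplicity is
    governed by the one-per-fragment constraint, not by clashes).
    """
    if mode not in ("energy", "geometric"):
        raise ConfigurationError(f"unknown pair-term mode {mode!r}")
    frag = pset.fragmentation
    calc = UFFPairEnergies(pset) if mode == "energy" else None
    terms: list[PairTerm] = []
    rows = []
    for pi, pj in combinations(pset.placements, 2):
        if pi.fragment_id == pj.fragment_id:
            continue
        enb_val = eb_val = float("nan")
        if mode == "geometric":
            term = geometric_pair_term(frag, pi, pj, clash_distance, bond_window)
        else:
            term = (
                pair_prefilter(frag, pi, pj, prefilter_cutoff)
                if prefilter_cutoff is not None
                else None
            )
            if term is None:
                enb_val = calc.enb(pi, pj)
                eb_val = (
                    calc.eb(pi, pj)
                    if frag.are_bonded(pi.fragment_id, pj.fragment_id)
                    else float("nan")
                )
                pe = PairEnergy(
                    pi.index,
                    pj.index,
                    enb_val,
                    None if np.isnan(eb_val) else eb_val,
                )
                term = binarize([pe], tol)[0]
        terms.append(term)
        rows.append(
            {
                "i": term.i,
                "j": term.j,
                "ENB": enb_val,
                "EB": eb_val,
                "clash": term.clash,
                "conn": term.conn,
            }
        )
    table = pd.DataFrame(rows, columns=["i", "j", "ENB", "EB", "clash", "conn"])
    return terms, table
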