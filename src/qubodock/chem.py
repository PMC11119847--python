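"""Compound handling and decomposition into rigid, hydrogen-capped fragments.

A compound is cut at every rotatable bond -- a single, non-ring bond between
two heavy atoms that each have at least two heavy neighbours -- and every open
valence is capped with a hydrogen.  Cutting alone can strand a lone linker
carbon (e.g. the CH2 groups of zopolrestat) as a one-atom fragment; such
singletons are merged back into a neighbouring fragment so that every fragment
is a chemically sensible rigid unit.  Attachment records link each cap
hydrogen to the partner fragment so the parent compound can be re-formed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .errors import FormatError, ValidationError

# Bond length used when placing a cap hydrogen along a former bond direction.
CAP_XH_LENGTH = 1.09  # Angstrom

PROP_PARENT_IDX = "parent_idx"
PROP_IS_CAP = "is_cap"


@dataclass
class Compound:
    """A sanitized molecule, optionally with 3D coordinates (Angstrom)."""

    mol: Chem.Mol
    name: str = ""

    @property
    def has_coordinates(self) -> bool:
        return self.mol.GetNumConformers() > 0

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(Chem.RemoveHs(self.mol))


@dataclass
class AttachmentRecord:
    """One end of an inter-fragment bond, seen from one fragment.

    ``heavy_atom`` and ``cap_hydrogen`` are atom indices in this fragment's
    capped molecule; ``partner_heavy_atom`` is an index in the partner
    fragment's capped molecule.  Records come in reciprocal pairs.
    """

    heavy_atom: int
    cap_hydrogen: int
    partner_fragment: int
    partner_heavy_atom: int


@dataclass
class Fragment:
    """A rigid, hydrogen-capped substructure of a parent compound."""

    fragment_id: int
    mol: Chem.Mol
    smiles: str
    parent_atom_map: dict[int, int]
    attachments: list[AttachmentRecord] = field(default_factory=list)

    @property
    def heavy_atom_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    @property
    def cap_hydrogen_indices(self) -> list[int]:
        return [
            a.GetIdx()
            for a in self.mol.GetAtoms()
            if a.HasProp(PROP_IS_CAP) and a.GetIntProp(PROP_IS_CAP)
        ]

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def coordinates(self) -> np.ndarray:
        if self.mol.GetNumConformers() == 0:
            raise ValidationError(f"fragment {self.fragment_id} has no conformer")
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)


@dataclass
class FragmentationResult:
    """Fragments of a compound plus the inter-fragment bond topology."""

    fragments: list[Fragment]
    bonds: list[tuple[int, int]]
    parent: Compound

    @property
    def num_fragments(self) -> int:
        return len(self.fragments)

    def attachment_for_bond(self, k1: int, k2: int) -> AttachmentRecord:
        """Attachment record of fragment ``k1`` for its bond to ``k2``."""
        for rec in self.fragments[k1].attachments:
            if rec.partner_fragment == k2:
                return rec
        raise ValidationError(f"fragments {k1} and {k2} are not bonded")

    def are_bonded(self, k1: int, k2: int) -> bool:
        return (k1, k2) in self._bondset or (k2, k1) in self._bondset

    @property
    def _bondset(self) -> set[tuple[int, int]]:
        return set(self.bonds)


def load_compound(source: str, name: str = "") -> Compound:
    """Load a compound from a SMILES string or an SDF/MOL file path.

    Coordinates present in an SDF/MOL record are preserved.  Raises
    :class:`FormatError` for unparsable input and :class:`ValidationError`
    for a disconnected molecular graph.
    """
    mol = None
    if os.path.exists(source):
        ext = os.path.splitext(source)[1].lower()
        if ext == ".sdf":
            supplier = Chem.SDMolSupplier(source, removeHs=False)
            mols = [m for m in supplier if m is not None]
            if not mols:
                raise FormatError(f"no parsable record in {source}")
            mol = mols[0]
        else:
            mol = Chem.MolFromMolFile(source, removeHs=False)
        if mol is None:
            raise FormatError(f"could not parse molecule file {source}")
        if not name and mol.HasProp("_Name"):
            name = mol.GetProp("_Name")
    else:
        mol = Chem.MolFromSmiles(source)
        if mol is None:
            raise FormatError(f"could not parse SMILES {source!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise FormatError(f"sanitization failed: {exc}") from exc
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValidationError("molecular graph is disconnected")
    return Compound(mol=mol, name=name or source)


def _heavy_degree(atom: Chem.Atom) -> int:
    return sum(1 for n in atom.GetNeighbors() if n.GetAtomicNum() > 1)


def find_cut_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Rotatable bonds eligible for cutting: single, acyclic, both heavy
    end atoms with >=2 heavy neighbours (no cuts into terminal groups)."""
    cuts = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
            continue
        if _heavy_degree(a) >= 2 and _heavy_degree(b) >= 2:
            cuts.append((a.GetIdx(), b.GetIdx()))
    return cuts


def _components(mol: Chem.Mol, cuts: list[tuple[int, int]]) -> list[set[int]]:
    """Connected heavy-atom components after removing the cut bonds, with
    one-heavy-atom components merged into a neighbour.

    Merge preference for a stranded single atom: carbon attachment atom over
    heteroatom, ring atom over acyclic, larger component, lower atom index.
    """
    import networkx as nx

    g = nx.Graph()
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    g.add_nodes_from(heavy)
    cutset = {frozenset(c) for c in cuts}
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in g and j in g and frozenset((i, j)) not in cutset:
            g.add_edge(i, j)
    comps = [set(c) for c in nx.connected_components(g)]

    def comp_of(idx: int) -> int:
        return next(k for k, c in enumerate(comps) if idx in c)

    merged = True
    while merged:
        merged = False
        for k, comp in enumerate(comps):
            if len(comp) != 1:
                continue
            (i,) = comp
            choices = []
            for a, b in cuts:
                if i in (a, b):
                    j = b if a == i else a
                    at = mol.GetAtomWithIdx(j)
                    choices.append(
                        (
                            0 if at.GetAtomicNum() == 6 else 1,
                            0 if at.IsInRing() else 1,
                            -len(comps[comp_of(j)]),
                            j,
                        )
                    )
            if not choices:
                break  # a genuinely isolated atom: keep as its own fragment
            choices.sort()
            target = comp_of(choices[0][3])
            comps[target].update(comp)
            comps.pop(k)
            merged = True
            break
    # deterministic order: by smallest parent atom index
    comps.sort(key=min)
    return comps


def decompose(compound: Compound) -> FragmentationResult:
    """Decompose a compound into rigid hydrogen-capped fragments.

    Every open valence created by a cut is capped with exactly one hydrogen
    (flagged with the ``is_cap`` atom property); each fragment atom carries a
    ``parent_idx`` property pointing back to the parent atom.  A compound with
    no cuttable bond yields a single fragment.
    """
    has3d = compound.has_coordinates
    molH = Chem.AddHs(compound.mol, addCoords=has3d)
    Chem.Kekulize(molH, clearAromaticFlags=False)
    cuts = find_cut_bonds(molH)
    comps = _components(molH, cuts)
    boundary = [
        (a, b)
        for a, b in cuts
        if _comp_index(comps, a) != _comp_index(comps, b)
    ]

    conf = molH.GetConformer() if has3d else None
    fragments: list[Fragment] = []
    local_index: list[dict[int, int]] = []  # per fragment: parent idx -> local idx
    cap_index: list[dict[tuple[int, int], int]] = []  # (heavy, partner) -> cap idx

    for fid, comp in enumerate(comps):
        atoms = sorted(comp)
        # hydrogens attached to this component travel with it
        for idx in list(atoms):
            for nb in molH.GetAtomWithIdx(idx).GetNeighbors():
                if nb.GetAtomicNum() == 1:
                    atoms.append(nb.GetIdx())
        rw = Chem.RWMol()
        lmap: dict[int, int] = {}
        coords: list[tuple[float, float, float]] = []
        for idx in atoms:
            src = molH.GetAtomWithIdx(idx)
            at = Chem.Atom(src.GetAtomicNum())
            at.SetFormalCharge(src.GetFormalCharge())
            at.SetNoImplicit(True)
            at.SetIntProp(PROP_PARENT_IDX, idx)
            lmap[idx] = rw.AddAtom(at)
            if conf is not None:
                p = conf.GetAtomPosition(idx)
                coords.append((p.x, p.y, p.z))
        for bond in molH.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in lmap and j in lmap:
                rw.AddBond(lmap[i], lmap[j], bond.GetBondType())
        # cap hydrogens, one per boundary bond touching this component
        caps: dict[tuple[int, int], int] = {}
        for a, b in boundary:
            for heavy, partner in ((a, b), (b, a)):
                if heavy in comp:
                    h = Chem.Atom(1)
                    h.SetNoImplicit(True)
                    h.SetIntProp(PROP_IS_CAP, 1)
                    cap = rw.AddAtom(h)
                    rw.AddBond(lmap[heavy], cap, Chem.BondType.SINGLE)
                    caps[(heavy, partner)] = cap
                    if conf is not None:
                        ph = np.array(conf.GetAtomPosition(heavy))
                        pp = np.array(conf.GetAtomPosition(partner))
                        d = pp - ph
                        d /= np.linalg.norm(d)
                        coords.append(tuple(ph + CAP_XH_LENGTH * d))
        frag_mol = rw.GetMol()
        Chem.SanitizeMol(frag_mol)
        if conf is not None:
            fconf = Chem.Conformer(frag_mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(coords):
                fconf.SetAtomPosition(i, Point3D(x, y, z))
            frag_mol.AddConformer(fconf, assignId=True)
        smiles = Chem.MolToSmiles(Chem.RemoveHs(frag_mol))
        fragments.append(
            Fragment(
                fragment_id=fid,
                mol=frag_mol,
                smiles=smiles,
                parent_atom_map={v: k for k, v in lmap.items()},
            )
        )
        local_index.append(lmap)
        cap_index.append(caps)

    bonds: list[tuple[int, int]] = []
    for a, b in boundary:
        ka, kb = _comp_index(comps, a), _comp_index(comps, b)
        bonds.append((min(ka, kb), max(ka, kb)))
        fragments[ka].attachments.append(
            AttachmentRecord(
                heavy_atom=local_index[ka][a],
                cap_hydrogen=cap_index[ka][(a, b)],
                partner_fragment=kb,
                partner_heavy_atom=local_index[kb][b],
            )
        )
        fragments[kb].attachments.append(
            AttachmentRecord(
                heavy_atom=local_index[kb][b],
                cap_hydrogen=cap_index[kb][(b, a)],
                partner_fragment=ka,
                partner_heavy_atom=local_index[ka][a],
            )
        )
    return FragmentationResult(fragments=fragments, bonds=sorted(bonds), parent=compound)


def _comp_index(comps: list[set[int]], atom_idx: int) -> int:
    for k, c in enumerate(comps):
        if atom_idx in c:
            return k
    raise ValidationError(f"atom {atom_idx} not in any component")


def write_fragments_sdf(fragmentation: FragmentationResult, path: str) -> None:
    """Write fragments as a multi-record SDF with bookkeeping properties."""
    writer = Chem.SDWriter(path)
    try:
        for frag in fragmentation.fragments:
            mol = Chem.Mol(frag.mol)
            mol.SetProp("_Name", f"fragment_{frag.fragment_id}")
            mol.SetIntProp("fragment_id", frag.fragment_id)
            mol.SetProp("parent_id", fragmentation.parent.name)
            mol.SetProp("capped_smiles", frag.smiles)
            mol.SetProp(
                "attachments",
                json.dumps(
                    [
                        {
                            "heavy_atom": r.heavy_atom,
                            "cap_hydrogen": r.cap_hydrogen,
                            "partner_fragment": r.partner_fragment,
                            "partner_heavy_atom": r.partner_heavy_atom,
                        }
                        for r in frag.attachments
                    ]
                ),
            )
            writer.write(mol)
    finally:
        writer.close()


def fragmentation_summary(fragmentation: FragmentationResult) -> dict:
    return {
        "parent": fragmentation.parent.name,
        "num_fragments": fragmentation.num_fragments,
        "fragments": [
            {
                "fragment_id": f.fragment_id,
                "smiles": f.smiles,
                "num_heavy_atoms": len(f.heavy_atom_indices),
                "attachments": len(f.attachments),
            }
            for f in fragmentation.fragments
        ],
        "bonds": [list(b) for b in fragmentation.bonds],
    }
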