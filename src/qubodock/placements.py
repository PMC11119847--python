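"""Candidate fragment placements and the docking-region bookkeeping.

The docking box is tiled into cubic subregions (2 Angstrom cells by default,
343 cells for the 14 Angstrom box used in the redocking experiment).  Poses
produced by an external fragment-docking run (or by the synthetic generator)
are ingested with a negative-score filter, a per-fragment per-subregion cap on
the best-scoring poses, and a cross-subregion RMSD deduplication that keeps
the best-scoring representative of every cluster of near-identical poses.
Each surviving placement becomes one binary variable of the QUBO.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import FragmentationResult
from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 0.0  # kcal/mol; keep only negative (favourable) scores
DEFAULT_POSES_PER_CAP = 20
DEFAULT_DEDUP_RMSD = 1.0  # Angstrom


@dataclass(frozen=True)
class DockingRegion:
    """Cubic docking box centred on the binding site, tiled into cells."""

    center: tuple[float, float, float]
    edge: float
    cell: float

    def __post_init__(self):
        if self.edge <= 0 or self.cell <= 0:
            raise ConfigurationError("box and cell edges must be positive")
        if self.cell > self.edge:
            raise ConfigurationError("cell edge cannot exceed box edge")

    @property
    def cells_per_axis(self) -> int:
        n = self.edge / self.cell
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"box edge {self.edge} is not a multiple of cell edge {self.cell}"
            )
        return int(round(n))

    @property
    def corner(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float) - self.edge / 2.0

    def subregion_of(self, point: np.ndarray) -> tuple[int, int, int] | None:
        """Index triple of the half-open cell [lo, hi) containing ``point``,
        or None if the point lies outside the box."""
        rel = (np.asarray(point, dtype=float) - self.corner) / self.cell
        idx = np.floor(rel).astype(int)
        n = self.cells_per_axis
        if np.any(idx < 0) or np.any(idx >= n):
            return None
        return tuple(int(i) for i in idx)


@dataclass(frozen=True)
class Subregion:
    index: tuple[int, int, int]
    center: tuple[float, float, float]


def enumerate_subregions(region: DockingRegion) -> list[Subregion]:
    """All cells tiling the box, ordered lexicographically by index."""
    n = region.cells_per_axis
    corner = region.corner
    subs = []
    for ix in range(n):
        for iy in range(n):
            for iz in range(n):
                center = corner + (np.array([ix, iy, iz]) + 0.5) * region.cell
                subs.append(Subregion((ix, iy, iz), tuple(center)))
    return subs


@dataclass
class Placement:
    """One rigid 3D pose of one fragment; the unit mapped to a QUBO variable.

    ``coords`` covers all atoms of the fragment's capped molecule (including
    cap hydrogens), in the fragment's atom order.  ``score`` is the binding
    free energy estimate dG_i in kcal/mol (negative is favourable).
    """

    index: int
    fragment_id: int
    coords: np.ndarray
    score: float
    subregion: tuple[int, int, int] | None = None

    def heavy_coords(self, fragmentation: FragmentationResult) -> np.ndarray:
        idx = fragmentation.fragments[self.fragment_id].heavy_atom_indices
        return self.coords[idx]

    def centroid(self, fragmentation: FragmentationResult) -> np.ndarray:
        return self.heavy_coords(fragmentation).mean(axis=0)


@dataclass
class PlacementSet:
    """Ordered placements with the fragment -> variable grouping S_k."""

    placements: list[Placement]
    fragmentation: FragmentationResult
    groups: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.groups:
            self._rebuild_groups()

    def _rebuild_groups(self):
        self.groups = {f.fragment_id: [] for f in self.fragmentation.fragments}
        for p in self.placements:
            self.groups[p.fragment_id].append(p.index)

    def __len__(self) -> int:
        return len(self.placements)

    def __getitem__(self, i: int) -> Placement:
        return self.placements[i]

    def scores(self) -> np.ndarray:
        return np.array([p.score for p in self.placements], dtype=float)

    def reindexed(self) -> "PlacementSet":
        """Renumber placements densely 0..n-1 preserving order."""
        new = [
            Placement(i, p.fragment_id, p.coords, p.score, p.subregion)
            for i, p in enumerate(self.placements)
        ]
        return PlacementSet(new, self.fragmentation)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.placements:
            c = p.centroid(self.fragmentation)
            rows.append(
                {
                    "id": p.index,
                    "fragment_id": p.fragment_id,
                    "score": p.score,
                    "subregion": "" if p.subregion is None else
                    f"{p.subregion[0]},{p.subregion[1]},{p.subregion[2]}",
                    "cx": c[0],
                    "cy": c[1],
                    "cz": c[2],
                }
            )
        return pd.DataFrame(
            rows, columns=["id", "fragment_id", "score", "subregion", "cx", "cy", "cz"]
        )


def _pose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """In-place (no superposition) RMSD between identically ordered coords."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def ingest_poses(
    poses: "str | list[tuple[int, np.ndarray, float]]",
    fragmentation: FragmentationResult,
    region: DockingRegion | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    per_subregion_cap: int = DEFAULT_POSES_PER_CAP,
) -> PlacementSet:
    """Build a PlacementSet from docked fragment poses.

    ``poses`` is either a path to a multi-record SDF (properties
    ``fragment_id`` and ``score``) or a list of ``(fragment_id, coords,
    score)`` tuples.  Poses with ``score >= score_threshold`` are dropped;
    poses whose heavy-atom centroid falls outside the region are dropped with
    a warning; per fragment and subregion at most ``per_subregion_cap``
    best-scoring poses are kept.
    """
    records: list[tuple[int, np.ndarray, float]] = (
        _read_pose_sdf(poses, fragmentation) if isinstance(poses, str) else list(poses)
    )
    nfrag = fragmentation.num_fragments
    kept: dict[tuple[int, tuple | None], list[tuple[float, int, np.ndarray]]] = {}
    for order, (fid, coords, score) in enumerate(records):
        if not (0 <= fid < nfrag):
            raise ValidationError(f"pose references unknown fragment {fid}")
        coords = np.asarray(coords, dtype=float)
        nat = fragmentation.fragments[fid].num_atoms
        if coords.shape != (nat, 3):
            raise ValidationError(
                f"pose for fragment {fid} has shape {coords.shape}, expected ({nat}, 3)"
            )
        if score >= score_threshold:
            continue
        sub = None
        if region is not None:
            heavy = coords[fragmentation.fragments[fid].heavy_atom_indices]
            sub = region.subregion_of(heavy.mean(axis=0))
            if sub is None:
                warnings.warn(
                    f"pose {order} (fragment {fid}) centroid outside docking box; dropped",
                    stacklevel=2,
                )
                continue
        kept.setdefault((fid, sub), []).append((score, order, coords))
    placements: list[Placement] = []
    for (fid, sub), bucket in sorted(kept.items(), key=lambda kv: (kv[0][0], kv[0][1] or ())):
        bucket.sort(key=lambda t: (t[0], t[1]))
        for score, _, coords in bucket[:per_subregion_cap]:
            placements.append(Placement(len(placements), fid, coords, score, sub))
    return PlacementSet(placements, fragmentation)


def _read_pose_sdf(
    path: str, fragmentation: FragmentationResult
) -> list[tuple[int, np.ndarray, float]]:
    supplier = Chem.SDMolSupplier(path, removeHs=False)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise FormatError(f"unparsable record {i} in {path}")
        if not mol.HasProp("fragment_id"):
            raise FormatError(f"record {i} in {path} lacks a fragment_id property")
        if not mol.HasProp("score"):
            raise FormatError(f"record {i} in {path} lacks a score property")
        fid = int(mol.GetProp("fragment_id"))
        score = float(mol.GetProp("score"))
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        out.append((fid, coords, score))
    return out


def dedup(pset: PlacementSet, rmsd_threshold: float = DEFAULT_DEDUP_RMSD) -> PlacementSet:
    """Best-score-first greedy RMSD deduplication within each fragment.

    Placements are visited in order of ascending score; a placement is kept
    iff its heavy-atom in-place RMSD to every already kept placement of the
    same fragment is >= ``rmsd_threshold``.  The global best placement of
    every fragment always survives.
    """
    if rmsd_threshold <= 0:
        raise ConfigurationError("rmsd threshold must be positive")
    survivors: list[Placement] = []
    for fid in sorted(pset.groups):
        members = [pset[i] for i in pset.groups[fid]]
        members.sort(key=lambda p: (p.score, p.index))
        heavy_idx = pset.fragmentation.fragments[fid].heavy_atom_indices
        accepted: list[Placement] = []
        for p in members:
            hc = p.coords[heavy_idx]
            if all(
                _pose_rmsd(hc, q.coords[heavy_idx]) >= rmsd_threshold for q in accepted
            ):
                accepted.append(p)
        survivors.extend(sorted(accepted, key=lambda p: p.index))
    survivors.sort(key=lambda p: p.index)
    out = PlacementSet(survivors, pset.fragmentation).reindexed()
    logger.info("dedup: %d -> %d placements", len(pset), len(out))
    return out


def write_placements_sdf(pset: PlacementSet, path: str) -> None:
    """Consolidated SDF of the surviving placements with their properties."""
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(path)
    try:
        for p in pset.placements:
            frag = pset.fragmentation.fragments[p.fragment_id]
            mol = Chem.Mol(frag.mol)
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z) in enumerate(p.coords):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
            mol.RemoveAllConformers()
            mol.AddConformer(conf, assignId=True)
            mol.SetProp("_Name", f"placement_{p.index}")
            mol.SetIntProp("placement_id", p.index)
            mol.SetIntProp("fragment_id", p.fragment_id)
            mol.SetDoubleProp("score", p.score)
            writer.write(mol)
    finally:
        writer.close()
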