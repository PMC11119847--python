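"""Planted synthetic docking instances for end-to-end testing and benchmarks.

The synthetic compound is a chain of K cyclopropyl rings joined by single
bonds: every ring is rigid (no internal rotatable bond), every ring-ring bond
is cuttable, so decomposition yields exactly K fragments in a linear chain --
the smallest real chemistry that exercises every downstream stage, including
the force-field pair energies.

A ground-truth pose is planted by embedding the whole chain in 3D: its
per-fragment coordinate slices become the planted placements, which are
feasible by construction (clash-free, consecutive attachment atoms at actual
bond length).  Each fragment additionally receives m-1 decoys: copies of the
planted pose under random rigid transforms.  Planted placements draw scores
from a favourable distribution, decoys from a broader, less favourable one,
mirroring the spread observed in real fragment-docking score tables (best
scores around -4 to -6 kcal/mol, worst near 0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from . import pairs as pairs_mod
from .chem import Compound, FragmentationResult, decompose
from .errors import GenerationError
from .pairs import PairTerm
from .placements import Placement, PlacementSet
from .qubo import Weights, build_qubo, evaluate

MAX_RETRIES = 20


@dataclass
class GeneratorConfig:
    """Stated world of the generator; defaults mirror the four-fragment
    redocking compound at desk scale."""

    n_fragments: int = 4
    placements_per_fragment: int = 5
    decoy_displacement: float = 3.0  # Angstrom, translation scale of decoys
    planted_score_mean: float = -6.0  # kcal/mol
    planted_score_sd: float = 0.5
    decoy_score_mean: float = -2.5
    decoy_score_sd: float = 1.5
    clash_density: float = 0.3  # fraction of decoys planted onto another fragment
    mode: str = "geometric"  # pair-term mode: "geometric" | "energy"
    dominated_decoys: bool = False  # decoys strictly worse and unconnectable
    seed: int = 0

    def __post_init__(self):
        if self.n_fragments < 1 or self.placements_per_fragment < 1:
            raise GenerationError("need at least one fragment and one placement each")
        if self.mode not in ("geometric", "energy"):
            raise GenerationError(f"unknown pair-term mode {self.mode!r}")


@dataclass
class SyntheticInstance:
    compound: Compound
    fragmentation: FragmentationResult
    placements: PlacementSet
    terms: list[PairTerm]
    planted: tuple[int, ...]
    config: GeneratorConfig
    weights: Weights = field(default_factory=Weights)

    def qubo(self):
        return build_qubo(self.placements, self.terms, self.weights)


def chain_smiles(k: int) -> str:
    """SMILES of a chain of ``k`` cyclopropyl rings."""
    return "C1CC1" * k


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _embed_chain(k: int, seed: int) -> Compound:
    mol = Chem.MolFromSmiles(chain_smiles(k))
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise GenerationError("3D embedding of the synthetic chain failed")
    AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    return Compound(mol=mol, name=f"synthetic_chain_{k}")


def generate_instance(config: GeneratorConfig) -> SyntheticInstance:
    """Build a planted instance; the planted selection is guaranteed valid
    (H4 = 0), clash-free, and fully connected along the chain."""
    rng = np.random.default_rng(int(config.seed))
    last_error = "no attempt made"
    for attempt in range(MAX_RETRIES):
        try:
            inst = _generate_once(config, rng)
        except GenerationError as exc:
            last_error = str(exc)
            continue
        qubo = inst.qubo()
        bd = evaluate(qubo, inst.planted)
        if bd.h4 == 0 and bd.h2 == 0 and bd.h3 == -(config.n_fragments - 1):
            return inst
        last_error = (
            f"planted vector infeasible (H2={bd.h2}, H3={bd.h3}, H4={bd.h4})"
        )
    raise GenerationError(
        f"could not generate a feasible instance after {MAX_RETRIES} attempts: "
        + last_error
    )


def _generate_once(
    config: GeneratorConfig, rng: np.random.Generator
) -> SyntheticInstance:
    k, m = config.n_fragments, config.placements_per_fragment
    compound = _embed_chain(k, seed=int(rng.integers(0, 2**31 - 1)))
    frag_result = decompose(compound)
    if frag_result.num_fragments != k:
        raise GenerationError(
            f"chain decomposed into {frag_result.num_fragments} fragments, expected {k}"
        )

    planted_coords = [f.coordinates() for f in frag_result.fragments]
    centroids = [
        c[frag_result.fragments[i].heavy_atom_indices].mean(axis=0)
        for i, c in enumerate(planted_coords)
    ]

    planted_scores = np.minimum(
        rng.normal(config.planted_score_mean, config.planted_score_sd, size=k), -0.01
    )
    records: list[tuple[int, np.ndarray, float]] = []
    planted_vector: list[int] = []
    idx = 0
    for fid in range(k):
        records.append((fid, planted_coords[fid], float(planted_scores[fid])))
        planted_vector.append(idx)
        idx += 1
        worst_planted = float(planted_scores.max())
        for _ in range(m - 1):
            coords = _decoy_coords(config, rng, frag_result, planted_coords, fid, centroids)
            if config.dominated_decoys:
                score = min(worst_planted + float(rng.uniform(0.5, 2.0)), -0.01)
            else:
                score = min(
                    float(rng.normal(config.decoy_score_mean, config.decoy_score_sd)),
                    -0.01,
                )
            records.append((fid, coords, score))
            idx += 1

    placements = [
        Placement(i, fid, coords, score) for i, (fid, coords, score) in enumerate(records)
    ]
    pset = PlacementSet(placements, frag_result)
    terms, _ = pairs_mod.compute_pair_terms(pset, mode=config.mode)
    if config.dominated_decoys:
        _check_decoys_unconnectable(terms, planted_vector, pset)
    x = np.zeros(len(pset), dtype=int)
    x[planted_vector] = 1
    return SyntheticInstance(
        compound=compound,
        fragmentation=frag_result,
        placements=pset,
        terms=terms,
        planted=tuple(int(v) for v in x),
        config=config,
    )


def _decoy_coords(
    config: GeneratorConfig,
    rng: np.random.Generator,
    frag_result: FragmentationResult,
    planted_coords: list[np.ndarray],
    fid: int,
    centroids: list[np.ndarray],
) -> np.ndarray:
    """Random rigid transform of the planted pose of fragment ``fid``.

    With probability ``clash_density`` the decoy is dropped onto the centroid
    of another fragment's planted pose (guaranteeing a steric clash there);
    in dominated mode the translation is forced away from the bond window so
    the decoy cannot form any chain bond.
    """
    base = planted_coords[fid]
    center = centroids[fid]
    rot = _random_rotation(rng)
    if config.clash_density > 0 and rng.random() < config.clash_density and len(centroids) > 1:
        others = [i for i in range(len(centroids)) if i != fid]
        target = centroids[int(rng.choice(others))]
        shift = target - center + rng.normal(0, 0.2, size=3)
    else:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        if config.dominated_decoys:
            radius = config.decoy_displacement + float(rng.uniform(3.0, 6.0))
        else:
            radius = abs(rng.normal(config.decoy_displacement, config.decoy_displacement / 2.0))
        shift = direction * radius
    return (base - center) @ rot.T + center + shift


def _check_decoys_unconnectable(
    terms: list[PairTerm], planted_vector: list[int], pset: PlacementSet
) -> None:
    planted = set(planted_vector)
    for t in terms:
        if t.conn == -1 and not ({t.i, t.j} <= planted):
            raise GenerationError("a decoy placement is connectable; resampling")


def scoreband_report(instance: SyntheticInstance) -> pd.DataFrame:
    """Per fragment: placement count and score band (min/max dG), the
    synthetic counterpart of a fragment-docking result table."""
    rows = []
    for fid in sorted(instance.placements.groups):
        members = [instance.placements[i] for i in instance.placements.groups[fid]]
        if not members:
            continue
        scores = [p.score for p in members]
        rows.append(
            {
                "fragment_id": fid,
                "fragment_smiles": instance.fragmentation.fragments[fid].smiles,
                "n_placements": len(members),
                "score_min": min(scores),
                "score_max": max(scores),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["fragment_id", "fragment_smiles", "n_placements", "score_min", "score_max"],
    )


def instance_fingerprint(instance: SyntheticInstance) -> str:
    """Deterministic text serialization of an instance (for reproducibility
    checks: identical config + seed must give identical fingerprints)."""
    buf = io.StringIO()
    buf.write(f"compound {instance.compound.smiles}\n")
    buf.write(f"planted {','.join(map(str, instance.planted))}\n")
    for p in instance.placements.placements:
        coords = ";".join(
            f"{x:.6f},{y:.6f},{z:.6f}" for x, y, z in np.asarray(p.coords)
        )
        buf.write(f"placement {p.index} {p.fragment_id} {p.score:.6f} {coords}\n")
    for t in instance.terms:
        buf.write(f"term {t.i} {t.j} {t.clash} {t.conn}\n")
    return buf.getvalue()
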