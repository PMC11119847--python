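"""QUBO minimizers: exhaustive oracle, simulated annealing, validity filter.

The annealer is a multi-restart single-bit-flip Metropolis scheme with a
geometric cooling schedule and a final zero-temperature quench; it stands in
for a proprietary quantum-inspired machine, whose only property relied on
here is that it emits many distinct local solutions.  Each restart runs on
its own deterministic random stream derived from (seed, restart index), so
enlarging the restart budget strictly extends the set of explored states.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, QuboDockError
from .qubo import HamiltonianBreakdown, QUBOProblem, evaluate, is_valid_selection

DEFAULT_RESTARTS = 200
DEFAULT_SWEEPS = 100
BRUTE_FORCE_MAX_VARS = 25


@dataclass
class Solution:
    """One selection vector with its Hamiltonian breakdown and provenance."""

    x: tuple[int, ...]
    breakdown: HamiltonianBreakdown
    valid: bool
    provenance: dict = field(default_factory=dict)

    @property
    def energy(self) -> float:
        return self.breakdown.total


@dataclass
class SolverConfig:
    """Reproducible annealing budget and schedule."""

    seed: int = 0
    restarts: int = DEFAULT_RESTARTS
    sweeps: int = DEFAULT_SWEEPS
    t_initial: float | None = None  # None: set from the max single-flip |dH|
    t_final_factor: float = 1e-3
    time_budget: float | None = None  # seconds; None = no wall-clock limit

    def __post_init__(self):
        if self.restarts < 0 or self.sweeps <= 0:
            raise ConfigurationError("restarts must be >= 0 and sweeps positive")


class SolutionPool:
    """Distinct solutions sorted by energy (ties broken lexicographically)."""

    def __init__(self, solutions: list[Solution] | None = None):
        self.solutions: list[Solution] = []
        self._seen: set[tuple[int, ...]] = set()
        self.meta: dict = {}
        for s in solutions or []:
            self.add(s)

    def add(self, sol: Solution) -> bool:
        if sol.x in self._seen:
            return False
        self._seen.add(sol.x)
        self.solutions.append(sol)
        self.solutions.sort(key=lambda s: (s.energy, s.x))
        return True

    def __len__(self) -> int:
        return len(self.solutions)

    def __iter__(self):
        return iter(self.solutions)

    def __getitem__(self, i: int) -> Solution:
        return self.solutions[i]

    @property
    def best(self) -> Solution:
        if not self.solutions:
            raise QuboDockError("empty solution pool")
        return self.solutions[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, s in enumerate(self.solutions):
            b = s.breakdown
            rows.append(
                {
                    "rank": rank,
                    "H": s.energy,
                    "H1": b.h1,
                    "H2": b.h2,
                    "H3": b.h3,
                    "H4": b.h4,
                    "valid": s.valid,
                    "bitstring": "".join(map(str, s.x)),
                }
            )
        return pd.DataFrame(
            rows, columns=["rank", "H", "H1", "H2", "H3", "H4", "valid", "bitstring"]
        )

    def to_json(self, path: str) -> None:
        payload = [
            {
                "x": list(s.x),
                "H": s.energy,
                "H1": s.breakdown.h1,
                "H2": s.breakdown.h2,
                "H3": s.breakdown.h3,
                "H4": s.breakdown.h4,
                "valid": s.valid,
                "provenance": s.provenance,
            }
            for s in self.solutions
        ]
        with open(path, "w") as fh:
            json.dump({"meta": self.meta, "solutions": payload}, fh, indent=1)


def _make_solution(qubo: QUBOProblem, x: np.ndarray, provenance: dict) -> Solution:
    xt = tuple(int(v) for v in x)
    if qubo.scores is not None and qubo.terms is not None:
        breakdown = evaluate(qubo, xt)
    else:
        # coefficient-only instance (e.g. read from a qbsolv/dense file):
        # the term-wise split is unavailable, carry the energy as H1
        from .qubo import Weights

        breakdown = HamiltonianBreakdown(
            qubo.energy(xt), 0.0, 0.0, 0.0, Weights(1.0, 0.0, 0.0, 0.0)
        )
        provenance = {**provenance, "breakdown": "energy-only"}
    valid = bool(qubo.groups) and is_valid_selection(qubo, xt)
    return Solution(xt, breakdown, valid, provenance)


def brute_force(
    qubo: QUBOProblem,
    max_vars: int = BRUTE_FORCE_MAX_VARS,
    top_k: int = 1000,
) -> SolutionPool:
    """Enumerate all 2^n selections; the pool's first element is the exact
    global optimum.  Refuses instances larger than ``max_vars``.  Energies of
    every vector are evaluated, but only the ``top_k`` best are materialized
    as Solution objects (the full 2^n pool would be impractically large)."""
    n = qubo.n
    if n > max_vars:
        raise QuboDockError(
            f"brute force refused: {n} variables exceeds the cap of {max_vars}"
        )
    pool = SolutionPool()
    pool.meta["solver"] = "brute_force"
    if n == 0:
        pool.add(_make_solution(qubo, np.zeros(0, dtype=int), {"solver": "brute_force"}))
        return pool
    h = qubo.linear
    a = qubo.interaction_matrix()
    chunk = 1 << min(n, 16)
    total = 1 << n
    best_codes: np.ndarray = np.empty(0, dtype=np.uint64)
    best_energies: np.ndarray = np.empty(0)
    shifts = np.arange(n, dtype=np.uint64)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint64)
        bits = ((codes[:, None] >> shifts) & np.uint64(1)).astype(float)
        energies = (
            qubo.offset
            + bits @ h
            + 0.5 * np.einsum("bi,ij,bj->b", bits, a, bits)
        )
        best_codes = np.concatenate([best_codes, codes])
        best_energies = np.concatenate([best_energies, energies])
        if len(best_energies) > top_k:
            keep = np.argpartition(best_energies, top_k)[:top_k]
            best_codes, best_energies = best_codes[keep], best_energies[keep]
    order = np.argsort(best_energies, kind="stable")
    for idx in order:
        row = ((best_codes[idx] >> shifts) & np.uint64(1)).astype(int)
        pool.add(_make_solution(qubo, row, {"solver": "brute_force"}))
    return pool


def _quench(x: np.ndarray, h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Greedy descent: flip any bit that lowers the energy until none does."""
    n = len(h)
    improved = True
    while improved:
        improved = False
        field_ = h + a @ x
        gains = (1.0 - 2.0 * x) * field_
        order = np.argsort(gains)
        for b in order:
            if gains[b] < 0:
                x[b] = 1.0 - x[b]
                improved = True
                break
    return x


def simulated_anneal(qubo: QUBOProblem, config: SolverConfig) -> SolutionPool:
    """Multi-restart Metropolis annealing; returns all distinct quenched
    final states, sorted by energy.  Fully reproducible for a fixed seed."""
    n = qubo.n
    pool = SolutionPool()
    pool.meta["solver"] = "simulated_annealing"
    pool.meta["config"] = {
        "seed": config.seed,
        "restarts": config.restarts,
        "sweeps": config.sweeps,
    }
    if config.restarts == 0:
        return pool
    if n == 0:
        pool.add(_make_solution(qubo, np.zeros(0, dtype=int), {"solver": "sa"}))
        return pool

    h = qubo.linear
    a = qubo.interaction_matrix()
    steps = config.sweeps * n
    t0 = config.t_initial
    if t0 is None:
        probe = np.random.default_rng([int(config.seed), 0x5EED]).integers(
            0, 2, size=n
        ).astype(float)
        dh = np.abs((1.0 - 2.0 * probe) * (h + a @ probe))
        t0 = max(float(dh.max()), 1.0)
    temps = t0 * (config.t_final_factor ** (np.arange(steps) / max(steps - 1, 1)))

    deadline = None if config.time_budget is None else time.monotonic() + config.time_budget
    restarts = config.restarts
    xs = np.empty((restarts, n))
    bits = np.empty((restarts, steps), dtype=np.int64)
    us = np.empty((restarts, steps))
    for r in range(restarts):
        rng = np.random.default_rng([int(config.seed), r])
        xs[r] = rng.integers(0, 2, size=n)
        bits[r] = rng.integers(0, n, size=steps)
        us[r] = rng.random(steps)

    ridx = np.arange(restarts)
    completed = restarts
    for s in range(steps):
        b = bits[:, s]
        de = (1.0 - 2.0 * xs[ridx, b]) * (h[b] + np.einsum("rj,rj->r", a[b], xs))
        accept = (de <= 0) | (us[:, s] < np.exp(-np.clip(de, 0, 700) / temps[s]))
        xs[ridx[accept], b[accept]] = 1.0 - xs[ridx[accept], b[accept]]
        if deadline is not None and time.monotonic() > deadline:
            break

    for r in range(completed):
        x = _quench(xs[r].copy(), h, a)
        pool.add(
            _make_solution(
                qubo,
                x,
                {"solver": "sa", "restart": r, "seed": int(config.seed)},
            )
        )
    return pool


def postprocess_filter(pool: SolutionPool, groups: dict[int, list[int]] | None = None) -> SolutionPool:
    """Keep only solutions selecting exactly one placement per fragment.

    ``groups`` defaults to the validity flags already carried by the
    solutions.  The retained fraction is recorded in ``pool.meta``.
    """
    out = SolutionPool()
    out.meta.update(pool.meta)
    for s in pool:
        if groups is None:
            ok = s.valid
        else:
            ok = all(sum(s.x[i] for i in g) == 1 for g in groups.values())
        if ok:
            out.add(s)
    out.meta["input_solutions"] = len(pool)
    out.meta["retained_solutions"] = len(out)
    out.meta["retained_fraction"] = (len(out) / len(pool)) if len(pool) else 0.0
    return out
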