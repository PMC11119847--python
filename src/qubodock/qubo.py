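"""Assembly and evaluation of the four-term docking Hamiltonian.

    H = A*H1 + B*H2 + C*H3 + D*H4

    H1 = sum_i dG_i x_i                         (fitness of accepted placements)
    H2 = sum_{i<j} clash(i,j) x_i x_j           (steric penalty)
    H3 = sum_{i<j} conn(i,j) x_i x_j            (covalent-bond reward)
    H4 = 1/2 sum_k (sum_{i in S_k} x_i - 1)^2
       + 1/2 sum_k sum_{i in S_k} x_i (1 - x_i) (one placement per fragment)

The pairwise sums run over unordered pairs, one contribution per pair; any
double-counting convention is absorbable into B and C.  The second H4 term
vanishes identically for binary x and contributes nothing to the QUBO
coefficients, but it is kept in the direct evaluator (it matters only to
continuous-relaxation solvers).  Expanding H4 with x^2 = x gives, per
fragment group S_k: -D/2 on each linear coefficient, +D on each intra-group
pair, and +D/2 on the constant offset -- so the QUBO energy of the all-zeros
vector is D*|F|/2 and H4 = 0 exactly on one-per-fragment selections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FormatError, ValidationError
from .pairs import PairTerm
from .placements import PlacementSet

DEFAULT_WEIGHTS = (1.0, 5.0, 5.0, 25.0)


@dataclass(frozen=True)
class Weights:
    """Term weights (A, B, C, D); defaults follow the reference experiment."""

    a: float = DEFAULT_WEIGHTS[0]
    b: float = DEFAULT_WEIGHTS[1]
    c: float = DEFAULT_WEIGHTS[2]
    d: float = DEFAULT_WEIGHTS[3]

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("weights must be non-negative")


@dataclass
class HamiltonianBreakdown:
    """Term-wise values of the Hamiltonian for one selection vector."""

    h1: float
    h2: float
    h3: float
    h4: float
    weights: Weights

    @property
    def total(self) -> float:
        w = self.weights
        return w.a * self.h1 + w.b * self.h2 + w.c * self.h3 + w.d * self.h4


@dataclass
class QUBOProblem:
    """Explicit QUBO with tracked offset and the variable bookkeeping.

    ``quad`` maps unordered index pairs (i < j) to coefficients.  ``groups``
    maps fragment id -> variable ids (the sets S_k).  ``scores`` and ``terms``
    retain the raw ingredients so the Hamiltonian can also be evaluated
    directly from its defining sums, independently of the coefficients.
    """

    n: int
    linear: np.ndarray
    quad: dict[tuple[int, int], float]
    offset: float
    groups: dict[int, list[int]]
    weights: Weights = field(default_factory=Weights)
    scores: np.ndarray | None = None
    terms: list[PairTerm] | None = None
    variable_fragments: list[int] | None = None

    def _check_vector(self, x) -> np.ndarray:
        x = np.asarray(x)
        if x.shape != (self.n,):
            raise ValidationError(f"selection vector must have length {self.n}")
        if not np.all((x == 0) | (x == 1)):
            raise ValidationError("selection vector entries must be 0 or 1")
        return x.astype(float)

    def energy(self, x) -> float:
        """QUBO-matrix evaluation: offset + h.x + sum_{i<j} J_ij x_i x_j."""
        x = self._check_vector(x)
        e = self.offset + float(self.linear @ x)
        for (i, j), v in self.quad.items():
            e += v * x[i] * x[j]
        return e

    def to_dense(self) -> tuple[np.ndarray, float]:
        """Symmetric matrix Q with h on the diagonal and J_ij/2 off-diagonal,
        so that x^T Q x + offset reproduces the energy."""
        q = np.zeros((self.n, self.n))
        np.fill_diagonal(q, self.linear)
        for (i, j), v in self.quad.items():
            q[i, j] += v / 2.0
            q[j, i] += v / 2.0
        return q, self.offset

    def interaction_matrix(self) -> np.ndarray:
        """Symmetric zero-diagonal matrix A with A[i, j] = J_ij (solver use)."""
        a = np.zeros((self.n, self.n))
        for (i, j), v in self.quad.items():
            a[i, j] = v
            a[j, i] = v
        return a


def build_qubo(
    pset: PlacementSet,
    terms: list[PairTerm],
    weights: Weights | None = None,
) -> QUBOProblem:
    """Assemble the QUBO coefficients from placements and pair terms."""
    w = weights or Weights()
    n = len(pset)
    scores = pset.scores()
    linear = w.a * scores.copy() if n else np.zeros(0)
    quad: dict[tuple[int, int], float] = {}

    def add_quad(i: int, j: int, v: float):
        if v == 0.0:
            return
        key = (min(i, j), max(i, j))
        quad[key] = quad.get(key, 0.0) + v

    for t in terms:
        if not (0 <= t.i < n and 0 <= t.j < n):
            raise ValidationError(f"pair term ({t.i}, {t.j}) references unknown variable")
        add_quad(t.i, t.j, w.b * t.clash + w.c * t.conn)

    offset = 0.0
    for fid, members in sorted(pset.groups.items()):
        offset += w.d / 2.0
        for i in members:
            linear[i] -= w.d / 2.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                add_quad(members[a], members[b], w.d)

    var_frag = [p.fragment_id for p in pset.placements]
    return QUBOProblem(
        n=n,
        linear=linear,
        quad=quad,
        offset=offset,
        groups={k: list(v) for k, v in pset.groups.items()},
        weights=w,
        scores=scores,
        terms=list(terms),
        variable_fragments=var_frag,
    )


def evaluate(qubo: QUBOProblem, x) -> HamiltonianBreakdown:
    """Direct term-by-term evaluation from the defining sums.

    Uses the unreduced formulas (including the identically vanishing second
    H4 term); agreement with :meth:`QUBOProblem.energy` is a standing
    cross-check of the coefficient expansion.
    """
    if qubo.scores is None or qubo.terms is None:
        raise ValidationError("instance lacks raw scores/terms for direct evaluation")
    xv = qubo._check_vector(x)
    h1 = float(qubo.scores @ xv)
    h2 = sum(t.clash * xv[t.i] * xv[t.j] for t in qubo.terms)
    h3 = sum(t.conn * xv[t.i] * xv[t.j] for t in qubo.terms)
    h4 = 0.0
    for members in qubo.groups.values():
        s = sum(xv[i] for i in members)
        h4 += 0.5 * (s - 1.0) ** 2
        h4 += 0.5 * sum(xv[i] * (1.0 - xv[i]) for i in members)
    return HamiltonianBreakdown(h1, float(h2), float(h3), h4, qubo.weights)


def is_valid_selection(qubo: QUBOProblem, x) -> bool:
    """True iff exactly one placement is selected for every fragment."""
    xv = qubo._check_vector(x)
    return all(sum(xv[i] for i in g) == 1 for g in qubo.groups.values())


# ---------------------------------------------------------------------------
# export / import

EXPORT_FORMATS = ("json", "qbsolv", "dense")


def export_qubo(qubo: QUBOProblem, path: str, format: str = "json") -> None:
    """Write the instance so an external annealer (or a round-trip read) can
    consume it.  JSON keeps the variable/fragment maps; qbsolv and dense
    keep only coefficients and offset."""
    if format not in EXPORT_FORMATS:
        raise ConfigurationError(f"unknown export format {format!r}")
    if format == "json":
        payload = {
            "n": qubo.n,
            "offset": qubo.offset,
            "linear": list(map(float, qubo.linear)),
            "quadratic": [[i, j, float(v)] for (i, j), v in sorted(qubo.quad.items())],
            "groups": {str(k): v for k, v in sorted(qubo.groups.items())},
            "variable_fragments": qubo.variable_fragments,
            "weights": [qubo.weights.a, qubo.weights.b, qubo.weights.c, qubo.weights.d],
            "scores": None if qubo.scores is None else list(map(float, qubo.scores)),
            "terms": None
            if qubo.terms is None
            else [[t.i, t.j, t.clash, t.conn] for t in qubo.terms],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif format == "qbsolv":
        lines = [f"c offset {float(qubo.offset)!r}"]
        nonzero_diag = [(i, float(v)) for i, v in enumerate(qubo.linear) if v != 0.0]
        lines.append(
            f"p qubo 0 {qubo.n} {len(nonzero_diag)} {len(qubo.quad)}"
        )
        for i, v in nonzero_diag:
            lines.append(f"{i} {i} {v!r}")
        for (i, j), v in sorted(qubo.quad.items()):
            lines.append(f"{i} {j} {float(v)!r}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:  # dense
        q, offset = qubo.to_dense()
        with open(path, "w") as fh:
            fh.write(f"{qubo.n} {float(offset)!r}\n")
            for row in q:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def import_qubo(path: str, format: str = "json") -> QUBOProblem:
    """Read an exported instance back; inverse of :func:`export_qubo`."""
    if format not in EXPORT_FORMATS:
        raise ConfigurationError(f"unknown export format {format!r}")
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        groups = {int(k): list(v) for k, v in payload["groups"].items()}
        quad = {(i, j): v for i, j, v in payload["quadratic"]}
        w = Weights(*payload["weights"])
        scores = payload.get("scores")
        terms = payload.get("terms")
        return QUBOProblem(
            n=payload["n"],
            linear=np.asarray(payload["linear"], dtype=float),
            quad=quad,
            offset=payload["offset"],
            groups=groups,
            weights=w,
            scores=None if scores is None else np.asarray(scores, dtype=float),
            terms=None
            if terms is None
            else [PairTerm(i, j, clash, conn) for i, j, clash, conn in terms],
            variable_fragments=payload.get("variable_fragments"),
        )
    if format == "qbsolv":
        offset = 0.0
        n = 0
        linear = None
        quad: dict[tuple[int, int], float] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0] == "c":
                    if len(parts) >= 3 and parts[1] == "offset":
                        offset = float(parts[2])
                elif parts[0] == "p":
                    n = int(parts[3])
                    linear = np.zeros(n)
                else:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                    if i == j:
                        linear[i] = v
                    else:
                        quad[(min(i, j), max(i, j))] = v
        if linear is None:
            raise FormatError(f"missing problem line in {path}")
        return QUBOProblem(n=n, linear=linear, quad=quad, offset=offset, groups={})
    # dense
    with open(path) as fh:
        header = fh.readline().split()
        n, offset = int(header[0]), float(header[1])
        q = np.array([[float(v) for v in fh.readline().split()] for _ in range(n)])
    linear = np.diag(q).copy()
    quad = {}
    for i in range(n):
        for j in range(i + 1, n):
            v = q[i, j] + q[j, i]
            if v != 0.0:
                quad[(i, j)] = v
    return QUBOProblem(n=n, linear=linear, quad=quad, offset=offset, groups={})
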