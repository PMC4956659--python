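"""Energy model and equilibrium ensemble computation.

The design algorithm is energy-model agnostic: it only needs, for any
sequence, the partition function Q, the augmented base-pair probability
matrix P, its nested / non-nested page split P' and P'', and the MFE
structure.  This module provides those through a configurable additive
pair-energy model (one energy per pair class AU / GC / GU, plus a
penalty per pseudoknot pair) and three interchangeable backends:

``exact``
    Exhaustive enumeration of the full two-page ensemble.  The ensemble
    size grows roughly like 2.4**n, so this backend is guarded to short
    sequences (default n <= 26); it is exact and serves as the oracle
    for everything else.
``nested``
    O(n^3)/O(n^4) inside-outside dynamic programming over the
    pseudoknot-free ensemble; handles sequences of hundreds of
    nucleotides.  P'' is identically zero.
``nupack``
    Adapter around an external folding program computing pseudoknot
    pair probabilities; only active when the binary is on PATH.

Per the backend contract, every backend returns the same matrices and
summary; callers never branch on backend identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from . import _kernels
from .structures import (
    MIN_LOOP_SPAN,
    PairedStructure,
    two_page_split,
    validate_sequence,
)

__all__ = [
    "KB",
    "EnergyModel",
    "DEFAULT_MODEL",
    "BackendUnavailable",
    "EnsembleSummary",
    "PairProbabilityMatrices",
    "EnsembleEvaluation",
    "free_energy",
    "pair_energy",
    "evaluate_ensemble",
    "pair_probability_matrices",
    "equilibrium_probability",
    "mfe_structure",
    "nested_partition_function",
    "enumerate_ensemble",
    "count_nested_structures",
    "BACKENDS",
]

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872


class BackendUnavailable(RuntimeError):
    """Raised when the requested thermodynamic backend cannot run."""


@dataclass(frozen=True)
class EnergyModel:
    """Additive pair-energy model.

    Parameters
    ----------
    pair_energies:
        kcal/mol per unordered pair class.  Defaults AU = -2.0,
        GC = -3.0, GU = -1.0 follow the usual stability ordering
        (GC > AU > GU) at magnitudes that keep desk-scale ensembles
        well-conditioned.
    pk_penalty:
        kcal/mol added per page-2 (pseudoknot) pair; a small positive
        default (+0.5) reflects the per-pair cost of crossing helices.
    pk_init:
        kcal/mol added once per pseudoknot (per connected component of
        the crossing graph with at least two pairs).  This is the
        initiation-penalty functional form of standard pseudoknot
        energy models; without it, any single spurious crossing pair is
        nearly free and the two-page ensemble is irreducibly diffuse,
        which would make low-defect design impossible at any scale.
        Default 3.5 exceeds the strongest pair energy (|GC| = 3.0), so
        isolated crossing pairs are always net-destabilizing while
        multi-pair pseudoknot helices remain favorable.
    temperature:
        Kelvin; 310.15 K (37 C) unless stated otherwise.
    thermal_energy:
        Explicit k_B*T override in kcal/mol; when None, computed as
        KB * temperature (~0.6163 kcal/mol at 37 C).

    The open chain has free energy 0 by convention.
    """

    pair_energies: Mapping[str, float] = field(
        default_factory=lambda: {"AU": -2.0, "GC": -3.0, "GU": -1.0}
    )
    pk_penalty: float = 0.5
    pk_init: float = 3.5
    temperature: float = 310.15
    thermal_energy: float | None = None

    def __post_init__(self) -> None:
        for key, val in self.pair_energies.items():
            if key not in ("AU", "GC", "GU"):
                raise ValueError(f"unknown pair class {key!r}")
            if not math.isfinite(val):
                raise ValueError(f"non-finite energy for pair class {key!r}")
        if self.kbt <= 0:
            raise ValueError("thermal energy must be positive")

    @property
    def kbt(self) -> float:
        return self.thermal_energy if self.thermal_energy is not None else KB * self.temperature


DEFAULT_MODEL = EnergyModel()

_PAIR_CLASS = {
    ("A", "U"): "AU", ("U", "A"): "AU",
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("G", "U"): "GU", ("U", "G"): "GU",
}


def pair_energy(model: EnergyModel, b1: str, b2: str) -> float | None:
    """Energy of the (b1, b2) pair, or None if the bases cannot pair."""
    cls = _PAIR_CLASS.get((b1, b2))
    if cls is None:
        return None
    return model.pair_energies[cls]


def _num_pseudoknots(structure: PairedStructure) -> int:
    """Connected components of the crossing graph with >= 2 pairs."""
    from .structures import pairs_cross

    plist = structure.sorted_pairs()
    m = len(plist)
    parent = list(range(m))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(m):
        for b in range(a + 1, m):
            if pairs_cross(plist[a], plist[b]):
                parent[find(a)] = find(b)
    sizes: dict[int, int] = {}
    for a in range(m):
        r = find(a)
        sizes[r] = sizes.get(r, 0) + 1
    return sum(1 for s in sizes.values() if s >= 2)


def free_energy(seq: str, structure: PairedStructure, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Free energy of a sequence folded into a fixed structure (kcal/mol).

    Sum of pair energies, plus ``pk_penalty`` per page-2 pair, plus
    ``pk_init`` once per pseudoknot (crossing component); the open chain
    scores 0.  Raises ValueError on an incompatible pair.
    """
    validate_sequence(seq, structure.n)
    total = 0.0
    for (i, j), pg in structure.page.items():
        e = pair_energy(model, seq[i - 1], seq[j - 1])
        if e is None:
            raise ValueError(
                f"bases {seq[i - 1]}-{seq[j - 1]} at pair ({i},{j}) cannot pair"
            )
        total += e
        if pg == 2:
            total += model.pk_penalty
    if model.pk_init and structure.has_pseudoknot:
        total += model.pk_init * _num_pseudoknots(structure)
    return total


def pair_energy_matrix(seq: str, model: EnergyModel) -> np.ndarray:
    """(n, n) matrix of pair energies, +inf where pairing is impossible."""
    n = len(seq)
    emat = np.full((n, n), np.inf, dtype=np.float64)
    for i in range(n):
        for j in range(i + MIN_LOOP_SPAN, n):
            e = pair_energy(model, seq[i], seq[j])
            if e is not None:
                emat[i, j] = e
                emat[j, i] = e
    return emat


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleSummary:
    """Partition function, ensemble size, and MFE of one sequence."""

    Q: float
    log_Q: float
    num_structures: int | None
    mfe_structure: PairedStructure
    mfe_energy: float


@dataclass(frozen=True)
class PairProbabilityMatrices:
    """Equilibrium pair-probability matrices of one sequence.

    ``P`` is n x (n+1): entry (i, j) is the probability that 1-based
    positions i+1, j+1 pair at equilibrium; the last column holds
    unpaired probabilities, so every row sums to 1.  ``P_nested`` (P')
    and ``P_nonnested`` (P'') split the first n columns by the canonical
    page of each pair in each structure; P' + P'' = P elementwise.
    """

    P: np.ndarray
    P_nested: np.ndarray
    P_nonnested: np.ndarray

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def unpaired_probability(self, i: int) -> float:
        """P(position i unpaired), 1-based i."""
        return float(self.P[i - 1, self.n])


@dataclass(frozen=True)
class EnsembleEvaluation:
    """Matrices plus summary, as produced by one backend evaluation."""

    matrices: PairProbabilityMatrices
    summary: EnsembleSummary
    backend: str


# ---------------------------------------------------------------------------
# Exact (two-page enumeration) backend
# ---------------------------------------------------------------------------

#: Sequences longer than this are refused by the exact backend: the
#: two-page ensemble grows exponentially (~1e7 structures near n = 24).
DEFAULT_MAX_ENUMERATION_N = 26


def _energy_shift(n: int, model: EnergyModel) -> float:
    """A lower bound on any structure energy of a length-n sequence."""
    emin = min(model.pair_energies.values())
    per_pair = min(0.0, emin) + min(0.0, model.pk_penalty) + min(0.0, model.pk_init)
    return (n // 2) * per_pair


def _structure_from_arrays(n: int, partner: np.ndarray, page2: np.ndarray) -> PairedStructure:
    pairs = {}
    for a in range(n):
        b = int(partner[a])
        if b > a:
            pairs[(a + 1, b + 1)] = 2 if page2[a] else 1
    return PairedStructure(n=n, pairs=frozenset(pairs), page=pairs)


def _evaluate_exact(
    seq: str,
    model: EnergyModel,
    pk_allowed: bool = True,
    max_n: int = DEFAULT_MAX_ENUMERATION_N,
) -> EnsembleEvaluation:
    n = len(seq)
    if n > max_n:
        raise ValueError(
            f"exact enumeration refused for n={n} > {max_n}; use the 'nested' "
            "backend or raise max_n explicitly"
        )
    emat = pair_energy_matrix(seq, model)
    eshift = _energy_shift(n, model)
    q_shift, count, P, P1, P2, mfe_partner, mfe_page2, mfe_energy = _kernels.enumerate_two_page(
        n, emat, model.kbt, model.pk_penalty, model.pk_init, eshift, pk_allowed
    )
    log_q = math.log(q_shift) - eshift / model.kbt
    mfe = _structure_from_arrays(n, mfe_partner, mfe_page2)
    summary = EnsembleSummary(
        Q=math.exp(log_q) if log_q < 700 else math.inf,
        log_Q=log_q,
        num_structures=int(count),
        mfe_structure=mfe,
        mfe_energy=float(mfe_energy),
    )
    matrices = PairProbabilityMatrices(P=P, P_nested=P1, P_nonnested=P2)
    return EnsembleEvaluation(matrices=matrices, summary=summary, backend="exact")


# ---------------------------------------------------------------------------
# Nested (pseudoknot-free DP) backend
# ---------------------------------------------------------------------------

def _nested_tables(seq: str, model: EnergyModel):
    """Inside table, scaled weights, and scale log for the nested DP."""
    n = len(seq)
    emat = pair_energy_matrix(seq, model)
    M = _kernels.nested_mfe_matrix(n, emat)
    mfe_energy = float(M[0, n])
    # per-nucleotide scale anchored at the MFE keeps the tables in range
    log_s = -mfe_energy / (n * model.kbt)
    kbt = model.kbt
    bs = np.where(np.isinf(emat), 0.0, np.exp(-emat / kbt - 2.0 * log_s))
    sinv = math.exp(-log_s)
    Qs = _kernels.nested_inside(n, bs, sinv)
    return emat, M, mfe_energy, log_s, bs, Qs


def _nested_mfe_traceback(seq: str, model: EnergyModel, emat: np.ndarray, M: np.ndarray) -> PairedStructure:
    """Lexicographically smallest dot-bracket among minimum-energy nested structures."""
    n = len(seq)
    tol = 1e-9
    memo: dict[tuple[int, int], str] = {}

    def smallest(i: int, j: int) -> str:  # segment [i, j] inclusive, 0-based
        if j < i:
            return ""
        key = (i, j)
        if key in memo:
            return memo[key]
        target = M[i, j + 1]
        best: str | None = None
        # pairing i gives '(' < '.', so explore pairings of the leftmost base first
        for k in range(i + MIN_LOOP_SPAN, j + 1):
            if np.isinf(emat[i, k]):
                continue
            if abs(emat[i, k] + M[i + 1, k] + M[k + 1, j + 1] - target) <= tol:
                cand = "(" + smallest(i + 1, k - 1) + ")" + smallest(k + 1, j)
                if best is None or cand < best:
                    best = cand
        if abs(M[i + 1, j + 1] - target) <= tol:
            cand = "." + smallest(i + 1, j)
            if best is None or cand < best:
                best = cand
        assert best is not None
        memo[key] = best
        return best

    from .structures import parse_dot_bracket

    return parse_dot_bracket(smallest(0, n - 1)) if n else PairedStructure(0, frozenset(), {})


def _evaluate_nested(seq: str, model: EnergyModel, **_ignored) -> EnsembleEvaluation:
    n = len(seq)
    emat, M, mfe_energy, log_s, bs, Qs = _nested_tables(seq, model)
    Qo = _kernels.nested_outside(n, bs, Qs)
    P = _kernels.nested_pair_probabilities(n, bs, Qs, Qo)
    log_q = math.log(Qs[0, n]) + n * log_s
    mfe = _nested_mfe_traceback(seq, model, emat, M)
    summary = EnsembleSummary(
        Q=math.exp(log_q) if log_q < 700 else math.inf,
        log_Q=log_q,
        num_structures=None,  # exact count available via count_nested_structures
        mfe_structure=mfe,
        mfe_energy=mfe_energy,
    )
    matrices = PairProbabilityMatrices(
        P=P, P_nested=P[:, :n].copy(), P_nonnested=np.zeros((n, n))
    )
    return EnsembleEvaluation(matrices=matrices, summary=summary, backend="nested")


def count_nested_structures(seq: str, model: EnergyModel = DEFAULT_MODEL) -> int:
    """Exact number of nested structures (arbitrary-precision integers)."""
    n = len(seq)
    allowed = [
        [pair_energy(model, seq[i], seq[j]) is not None for j in range(n)] for i in range(n)
    ]
    cnt: dict[tuple[int, int], int] = {}

    def c(i: int, j: int) -> int:  # segment [i, j] inclusive
        if j < i:
            return 1
        if (i, j) in cnt:
            return cnt[(i, j)]
        total = c(i, j - 1)
        for k in range(i, j - MIN_LOOP_SPAN + 1):
            if allowed[k][j]:
                total += c(i, k - 1) * c(k + 1, j - 1)
        cnt[(i, j)] = total
        return total

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * n + 100))
    try:
        return c(0, n - 1)
    finally:
        sys.setrecursionlimit(old)


def nested_partition_function(seq: str, model: EnergyModel = DEFAULT_MODEL) -> float:
    """Partition function over the pseudoknot-free ensemble (DP fast path).

    Identical in value to exhaustive enumeration with pk_allowed=False.
    """
    validate_sequence(seq)
    _, _, _, log_s, _, Qs = _nested_tables(seq, model)
    return float(Qs[0, len(seq)] * math.exp(len(seq) * log_s))


# ---------------------------------------------------------------------------
# External-folder adapter backend
# ---------------------------------------------------------------------------

def _evaluate_nupack(seq: str, model: EnergyModel, **kwargs) -> EnsembleEvaluation:
    from . import nupack_adapter

    return nupack_adapter.evaluate(seq, model, **kwargs)


BACKENDS = {
    "exact": _evaluate_exact,
    "nested": _evaluate_nested,
    "nupack": _evaluate_nupack,
}


def evaluate_ensemble(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    backend: str = "exact",
    **kwargs,
) -> EnsembleEvaluation:
    """Evaluate one sequence's equilibrium ensemble with the chosen backend."""
    validate_sequence(seq)
    try:
        fn = BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown backend {backend!r}; choose from {sorted(BACKENDS)}")
    return fn(seq, model, **kwargs)


def pair_probability_matrices(
    seq: str, model: EnergyModel = DEFAULT_MODEL, backend: str = "exact", **kwargs
) -> PairProbabilityMatrices:
    """Augmented P plus the nested / non-nested split P', P''."""
    return evaluate_ensemble(seq, model, backend, **kwargs).matrices


def equilibrium_probability(
    seq: str,
    target: PairedStructure,
    model: EnergyModel = DEFAULT_MODEL,
    backend: str = "exact",
    evaluation: EnsembleEvaluation | None = None,
    **kwargs,
) -> float:
    """Probability that the sequence folds into exactly the target structure.

    exp(-dG(seq, target)/kbt) / Q.  Pass a cached *evaluation* to avoid
    recomputing the partition function.  The value is clamped to [0, 1]:
    with the nested backend and a pseudoknotted target the target lies
    outside the backend's ensemble and the ratio is only a bound.
    """
    if evaluation is None:
        evaluation = evaluate_ensemble(seq, model, backend, **kwargs)
    dg = free_energy(seq, target, model)
    p = math.exp(-dg / model.kbt - evaluation.summary.log_Q)
    return min(1.0, p)


def mfe_structure(
    seq: str, model: EnergyModel = DEFAULT_MODEL, backend: str = "exact", **kwargs
) -> PairedStructure:
    """Minimum free-energy structure; energy ties break to the
    lexicographically smallest dot-bracket string."""
    return evaluate_ensemble(seq, model, backend, **kwargs).summary.mfe_structure


# ---------------------------------------------------------------------------
# Readable reference enumeration (per-structure access)
# ---------------------------------------------------------------------------

def _iter_matchings(
    seq: str, model: EnergyModel, pk_allowed: bool
) -> Iterator[list[tuple[int, int]]]:
    """Yield every admissible pair list (1-based) by simple recursion.

    This is the package's readable reference enumerator; the jitted
    kernel is cross-checked against it in the test suite.
    """
    n = len(seq)
    cands = [
        [
            j
            for j in range(i + MIN_LOOP_SPAN, n)
            if pair_energy(model, seq[i], seq[j]) is not None
        ]
        for i in range(n)
    ]
    partner = [-1] * n
    pairs: list[tuple[int, int]] = []

    def crossing_ok(new_pair: tuple[int, int]) -> bool:
        from .structures import StructureClassError

        if not pk_allowed:
            i, j = new_pair
            return not any(a < i < b < j for a, b in pairs)
        try:
            two_page_split([(a + 1, b + 1) for a, b in pairs + [new_pair]], n)
        except StructureClassError:
            return False
        return True

    def rec(pos: int) -> Iterator[list[tuple[int, int]]]:
        if pos == n:
            yield [(i + 1, j + 1) for i, j in pairs]
            return
        if partner[pos] != -1:
            yield from rec(pos + 1)
            return
        yield from rec(pos + 1)  # pos unpaired
        for j in cands[pos]:
            if partner[j] != -1:
                continue
            if not crossing_ok((pos, j)):
                continue
            pairs.append((pos, j))
            partner[pos] = j
            partner[j] = pos
            yield from rec(pos + 1)
            pairs.pop()
            partner[pos] = -1
            partner[j] = -1

    yield from rec(0)


def enumerate_ensemble(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    pk_allowed: bool = True,
    max_n: int = 20,
) -> tuple[EnsembleSummary, list[tuple[PairedStructure, float, float]]]:
    """Materialize the full ensemble: (structure, energy, probability) records.

    Practical only for short sequences (the guard defaults to n <= 20);
    per-structure probabilities sum to 1.  Page assignment of each
    structure is the canonical two-page split.
    """
    validate_sequence(seq)
    n = len(seq)
    if n > max_n:
        raise ValueError(f"ensemble enumeration refused for n={n} > {max_n}")
    records: list[tuple[PairedStructure, float]] = []
    for plist in _iter_matchings(seq, model, pk_allowed):
        page = two_page_split(plist, n)
        st = PairedStructure(n=n, pairs=frozenset(page), page=page)
        records.append((st, free_energy(seq, st, model)))
    kbt = model.kbt
    emin = min(e for _, e in records)
    weights = [math.exp(-(e - emin) / kbt) for _, e in records]
    q_shift = sum(weights)
    log_q = math.log(q_shift) + (-emin) / kbt
    full = [
        (st, e, w / q_shift) for (st, e), w in zip(records, weights)
    ]
    mfe_st, mfe_e, _ = min(full, key=lambda rec: (round(rec[1] / 1e-12), rec[0].dotbracket))
    summary = EnsembleSummary(
        Q=math.exp(log_q),
        log_Q=log_q,
        num_structures=len(records),
        mfe_structure=mfe_st,
        mfe_energy=mfe_e,
    )
    return summary, full
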