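"""Adaptive defect-weighted sampling designer.

Given a two-page target structure tau, the designer starts from a random
seed sequence compatible with tau, then iteratively mutates it, guided
by the equilibrium pair-probability matrices of the current candidate:

* operator 1 mutates one unpaired position i, accepted with probability
  1 - P[i, n+1] (its contribution to the ensemble defect);
* operator 2 mutates one target base pair (i, j), gated by 1 - P'[i, j]
  for nested pairs and 1 - P''[i, j] for non-nested (pseudoknot) pairs;
* operator 3 ("m-mutation") draws m ~ floor(|Normal(m', m'/5)|) with
  m' = N * n / C and applies m single/pair mutations in one iteration,
  so the mutation intensity adapts to the current normalized ensemble
  defect N.

At each iteration one operator is chosen uniformly from the applicable
subset; the loop stops when N <= f_stop or after max_it iterations, and
the fittest (lowest-N) candidate observed is returned.  A design
template locks conserved positions: they are copied into the seed and
are never mutated.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import (
    PARTNERS,
    DesignTemplate,
    PairedStructure,
    validate_template,
)
from .thermo import (
    DEFAULT_MODEL,
    EnergyModel,
    PairProbabilityMatrices,
    equilibrium_probability,
    evaluate_ensemble,
    free_energy,
)
from .metrics import ensemble_defect, structure_distance

__all__ = [
    "DesignConfig",
    "DesignResult",
    "IterationRecord",
    "OperatorInapplicable",
    "TemplateViolation",
    "initialize_seed",
    "mutate_single_nucleotide",
    "mutate_basepair",
    "compute_m",
    "m_mutation",
    "design",
    "run_trials",
]

#: Nested-pair replacement alphabet as the pair-mutation operator defines
#: it: only the three orientations A-U, G-C, G-U.
NESTED_PAIR_ALPHABET: tuple[tuple[str, str], ...] = (("A", "U"), ("G", "C"), ("G", "U"))
#: Non-nested pairs may take all six orientations.
FULL_PAIR_ALPHABET: tuple[tuple[str, str], ...] = (
    ("A", "U"), ("G", "C"), ("G", "U"), ("U", "A"), ("C", "G"), ("U", "G")
)


class OperatorInapplicable(RuntimeError):
    """A mutation operator has no mutable site on this target/template."""


class TemplateViolation(AssertionError):
    """A locked template position changed during sampling (internal error)."""


@dataclass(frozen=True)
class DesignConfig:
    """Inputs of one design run.

    f_stop and max_it default to the benchmark protocol values (0.01 and
    400); C = 5 is the adaptive divisor of the m-mutation operator.
    ``retry_cap`` bounds the rejection loops of operators 1-2: when every
    candidate site has near-zero acceptance probability (defect already
    tiny), after retry_cap draws the operator falls back to an ungated
    uniform site choice, keeping runtime bounded with unchanged behavior
    in non-degenerate regimes.  None means 100 * n.
    """

    f_stop: float = 0.01
    max_it: int = 400
    gc_content: float | None = None
    C: float = 5.0
    rng_seed: int | Sequence[int] = 0
    backend: str = "exact"
    adaptive_enabled: bool = True
    retry_cap: int | None = None
    nested_pair_all_orientations: bool = False
    model: EnergyModel = field(default_factory=lambda: DEFAULT_MODEL)
    track_trace: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.f_stop <= 1.0:
            raise ValueError("f_stop must lie in (0, 1]")
        if self.max_it < 1:
            raise ValueError("max_it must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.gc_content is not None and not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")


@dataclass(frozen=True)
class IterationRecord:
    """One sampling iteration: operator used, m (operator 3 only), and the
    metrics of the candidate after the mutation."""

    iteration: int
    operator: int
    m: int | None
    N: float
    pi: float


@dataclass(frozen=True)
class DesignResult:
    """Returned tuple of one design run plus its per-iteration trace."""

    sequence: str
    N: float
    pi: float
    dG: float
    mfe_defect: int
    boltzmann_frequency: float
    iterations_used: int
    elapsed_seconds: float
    reached_fstop: bool
    seed_sequence: str
    seed_N: float
    trace: tuple[IterationRecord, ...]


# ---------------------------------------------------------------------------
# Seed initialization
# ---------------------------------------------------------------------------

def _draw_pair_type(gc: float, rng: np.random.Generator) -> tuple[str, str]:
    """Joint draw of a free base pair: GC-class with probability gc."""
    if rng.random() < gc:
        return ("G", "C") if rng.random() < 0.5 else ("C", "G")
    return ("A", "U") if rng.random() < 0.5 else ("U", "A")


def _draw_partner_base(locked: str, gc: float, rng: np.random.Generator) -> str:
    """Base for the free end of a half-locked pair, biased toward gc."""
    options = PARTNERS[locked]
    if len(options) == 1:
        return options[0]
    gc_opts = [b for b in options if b in ("G", "C")]
    au_opts = [b for b in options if b not in ("G", "C")]
    if gc_opts and rng.random() < gc:
        return str(rng.choice(gc_opts))
    return str(rng.choice(au_opts or options))


def initialize_seed(
    target: PairedStructure,
    template: DesignTemplate | None = None,
    gc_content: float | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Random seed sequence compatible with the target.

    Locked template positions are copied verbatim; paired positions are
    drawn jointly as pair types so base-pairing rules hold; unconstrained
    positions approximate the requested GC fraction.  When gc_content is
    None a fraction is drawn uniformly from [0.20, 0.80] per seed.
    """
    rng = rng if rng is not None else np.random.default_rng()
    template = template if template is not None else DesignTemplate.all_open(target.n)
    template = validate_template(template, target)
    gc = gc_content if gc_content is not None else float(rng.uniform(0.20, 0.80))

    seq = [""] * target.n
    for i in template.locked_positions:
        seq[i - 1] = template.text[i - 1]
    for i, j in target.sorted_pairs():
        li, lj = template.is_locked(i), template.is_locked(j)
        if li and lj:
            continue  # validated to be an allowed pair already
        if li:
            seq[j - 1] = _draw_partner_base(seq[i - 1], gc, rng)
        elif lj:
            seq[i - 1] = _draw_partner_base(seq[j - 1], gc, rng)
        else:
            seq[i - 1], seq[j - 1] = _draw_pair_type(gc, rng)
    for i in target.unpaired_positions:
        if not template.is_locked(i):
            if rng.random() < gc:
                seq[i - 1] = "G" if rng.random() < 0.5 else "C"
            else:
                seq[i - 1] = "A" if rng.random() < 0.5 else "U"
    return "".join(seq)


# ---------------------------------------------------------------------------
# Mutation operators
# ---------------------------------------------------------------------------

def _mutable_unpaired(target: PairedStructure, template: DesignTemplate) -> list[int]:
    return [i for i in target.unpaired_positions if not template.is_locked(i)]


def _mutable_pairs(
    seq: str, target: PairedStructure, template: DesignTemplate
) -> list[tuple[int, int]]:
    """Target pairs with at least one end unlocked that can actually change."""
    out = []
    for i, j in target.sorted_pairs():
        li, lj = template.is_locked(i), template.is_locked(j)
        if li and lj:
            continue
        if li or lj:
            locked_base = seq[i - 1] if li else seq[j - 1]
            free_base = seq[j - 1] if li else seq[i - 1]
            if not [b for b in PARTNERS[locked_base] if b != free_base]:
                continue  # the free end has no alternative partner base
        out.append((i, j))
    return out


def mutate_single_nucleotide(
    seq: str,
    target: PairedStructure,
    P: PairProbabilityMatrices,
    template: DesignTemplate,
    rng: np.random.Generator,
    retry_cap: int | None = None,
) -> str:
    """Operator 1: mutate exactly one unpaired, unlocked position.

    Repeatedly draws a random unpaired position i, skips locked ones,
    and accepts i with probability 1 - P[i, n+1], i.e. proportionally to
    the position's contribution to the ensemble defect.  The new base is
    drawn uniformly from the three alternatives.
    """
    n = target.n
    unpaired = target.unpaired_positions
    mutable = _mutable_unpaired(target, template)
    if not mutable:
        raise OperatorInapplicable("target has no unpaired, unlocked position")
    cap = retry_cap if retry_cap is not None else 100 * n
    pos = 0
    for _ in range(cap):
        i = int(unpaired[rng.integers(len(unpaired))])
        if template.is_locked(i):
            continue
        if rng.random() < 1.0 - P.unpaired_probability(i):
            pos = i
            break
    else:
        pos = int(mutable[rng.integers(len(mutable))])  # degenerate-loop fallback
    alternatives = [b for b in "ACGU" if b != seq[pos - 1]]
    new_base = alternatives[rng.integers(3)]
    return seq[: pos - 1] + new_base + seq[pos:]


def _replace_pair(seq: str, i: int, j: int, bi: str, bj: str) -> str:
    chars = list(seq)
    chars[i - 1] = bi
    chars[j - 1] = bj
    return "".join(chars)


def _mutate_pair_bases(
    seq: str,
    i: int,
    j: int,
    template: DesignTemplate,
    alphabet: tuple[tuple[str, str], ...],
    rng: np.random.Generator,
) -> str:
    """Reassign pair (i, j), respecting one-end locks; never a no-op."""
    li, lj = template.is_locked(i), template.is_locked(j)
    if li or lj:
        locked_pos, free_pos = (i, j) if li else (j, i)
        locked_base = seq[locked_pos - 1]
        options = [b for b in PARTNERS[locked_base] if b != seq[free_pos - 1]]
        new_base = options[rng.integers(len(options))]
        return (
            _replace_pair(seq, i, j, locked_base, new_base)
            if li
            else _replace_pair(seq, i, j, new_base, locked_base)
        )
    current = (seq[i - 1], seq[j - 1])
    options = [pr for pr in alphabet if pr != current]
    bi, bj = options[rng.integers(len(options))]
    return _replace_pair(seq, i, j, bi, bj)


def mutate_basepair(
    seq: str,
    target: PairedStructure,
    P_nested: np.ndarray | PairProbabilityMatrices,
    P_nonnested: np.ndarray | None = None,
    template: DesignTemplate | None = None,
    rng: np.random.Generator | None = None,
    retry_cap: int | None = None,
    all_orientations: bool = False,
) -> str:
    """Operator 2: mutate the two ends of exactly one target pair.

    Draws a random target pair; pairs locked at both ends are skipped.
    A pair locked at one end mutates only the free end to a base forming
    an allowed pair, immediately and without a probability gate.  Fully
    free pairs are accepted with probability 1 - P'[i, j] (nested pairs,
    reassigned from {A-U, G-C, G-U}) or 1 - P''[i, j] (non-nested pairs,
    reassigned from all six orientations).
    """
    if isinstance(P_nested, PairProbabilityMatrices):
        P_nonnested = P_nested.P_nonnested
        P_nested = P_nested.P_nested
    assert P_nonnested is not None and template is not None and rng is not None
    n = target.n
    pairs = target.sorted_pairs()
    if not _mutable_pairs(seq, target, template):
        raise OperatorInapplicable("target has no mutable pair")
    nested_alpha = FULL_PAIR_ALPHABET if all_orientations else NESTED_PAIR_ALPHABET
    cap = retry_cap if retry_cap is not None else 100 * n
    for _ in range(cap):
        i, j = pairs[rng.integers(len(pairs))]
        li, lj = template.is_locked(i), template.is_locked(j)
        if li and lj:
            continue
        if li or lj:
            locked_base = seq[i - 1] if li else seq[j - 1]
            free_base = seq[j - 1] if li else seq[i - 1]
            if not [b for b in PARTNERS[locked_base] if b != free_base]:
                continue
            # half-locked pairs mutate immediately, without a defect gate
            return _mutate_pair_bases(seq, i, j, template, nested_alpha, rng)
        if target.page[(i, j)] == 1:
            gate = 1.0 - float(P_nested[i - 1, j - 1])
            alphabet = nested_alpha
        else:
            gate = 1.0 - float(P_nonnested[i - 1, j - 1])
            alphabet = FULL_PAIR_ALPHABET
        if rng.random() < gate:
            return _mutate_pair_bases(seq, i, j, template, alphabet, rng)
    # degenerate-loop fallback: ungated uniform choice among mutable pairs
    mutable = _mutable_pairs(seq, target, template)
    i, j = mutable[rng.integers(len(mutable))]
    alphabet = (
        nested_alpha if target.page[(i, j)] == 1 else FULL_PAIR_ALPHABET
    )
    return _mutate_pair_bases(seq, i, j, template, alphabet, rng)


def compute_m(N: float, n: int, C: float, rng: np.random.Generator) -> int:
    """Adaptive mutation count: m = floor(|Normal(m', m'/5)|), m' = N*n/C,
    clamped to at least 1."""
    if not 0.0 <= N <= 1.0:
        raise ValueError("N must lie in [0, 1]")
    m_prime = N * n / C
    m = int(math.floor(abs(rng.normal(m_prime, m_prime / 5.0)))) if m_prime > 0 else 0
    return max(m, 1)


def m_mutation(
    m: int,
    seq: str,
    target: PairedStructure,
    matrices: PairProbabilityMatrices,
    template: DesignTemplate,
    rng: np.random.Generator,
    retry_cap: int | None = None,
    all_orientations: bool = False,
) -> str:
    """Operator 3: apply exactly m counted positional mutations.

    Random positions decide the sub-operator: an unpaired draw triggers
    the single-nucleotide operator (+1 to the count), a paired draw the
    pair operator (+2).  When one mutation remains, the single operator
    is forced so the counted total lands exactly on m.  If the target
    offers only one operator class the applicable one substitutes (the
    count then caps at m).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    has_free = bool(_mutable_unpaired(target, template))
    has_pair = bool(_mutable_pairs(seq, target, template))
    if not has_free and not has_pair:
        raise OperatorInapplicable("no mutable site for m-mutation")
    partner = target.partner_array()
    count = 0
    while count < m:
        i = int(rng.integers(1, target.n + 1))
        want_single = count == m - 1 or partner[i - 1] < 0
        if want_single:
            if has_free:
                seq = mutate_single_nucleotide(seq, target, matrices, template, rng, retry_cap)
                count += 1
            else:
                seq = mutate_basepair(
                    seq, target, matrices, template=template, rng=rng,
                    retry_cap=retry_cap, all_orientations=all_orientations,
                )
                count = min(count + 2, m)
        else:
            if has_pair:
                seq = mutate_basepair(
                    seq, target, matrices, template=template, rng=rng,
                    retry_cap=retry_cap, all_orientations=all_orientations,
                )
                count += 2
            else:
                seq = mutate_single_nucleotide(seq, target, matrices, template, rng, retry_cap)
                count += 1
        has_pair = has_pair and bool(_mutable_pairs(seq, target, template))
    return seq


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def _check_template(seq: str, template: DesignTemplate) -> None:
    for i in template.locked_positions:
        if seq[i - 1] != template.text[i - 1]:
            raise TemplateViolation(
                f"locked position {i} changed to {seq[i - 1]!r}"
            )


def design(
    target: PairedStructure,
    template: DesignTemplate | str | None = None,
    config: DesignConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DesignResult:
    """Run one adaptive defect-weighted sampling trial.

    Returns the fittest (lowest normalized ensemble defect) candidate
    observed, with its probability defect, free energy on the target,
    MFE defect, Boltzmann frequency, iteration count and trace.
    """
    config = config if config is not None else DesignConfig()
    template = (
        DesignTemplate.all_open(target.n)
        if template is None
        else validate_template(template, target)
    )
    if len(template.locked_positions) == target.n:
        raise OperatorInapplicable("template locks every position: nothing to mutate")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    model = config.model
    t0 = time.perf_counter()

    seq = initialize_seed(target, template, config.gc_content, rng)
    evaluation = evaluate_ensemble(seq, model, config.backend)
    _, N = ensemble_defect(evaluation.matrices, target)
    pi = 1.0 - equilibrium_probability(seq, target, model, evaluation=evaluation)
    seed_seq, seed_N = seq, N
    best_seq, best_N, best_pi, best_eval = seq, N, pi, evaluation

    has_free = bool(_mutable_unpaired(target, template))
    has_pair = bool(_mutable_pairs(seq, target, template))
    trace: list[IterationRecord] = []
    it = 0
    while N > config.f_stop and it < config.max_it:
        it += 1
        ops = []
        if has_free:
            ops.append(1)
        if has_pair:
            ops.append(2)
        if config.adaptive_enabled and (has_free or has_pair):
            ops.append(3)
        op = ops[rng.integers(len(ops))]
        m: int | None = None
        if op == 1:
            seq = mutate_single_nucleotide(
                seq, target, evaluation.matrices, template, rng, config.retry_cap
            )
        elif op == 2:
            seq = mutate_basepair(
                seq, target, evaluation.matrices, template=template, rng=rng,
                retry_cap=config.retry_cap,
                all_orientations=config.nested_pair_all_orientations,
            )
        else:
            m = compute_m(N, target.n, config.C, rng)
            seq = m_mutation(
                m, seq, target, evaluation.matrices, template, rng,
                config.retry_cap, config.nested_pair_all_orientations,
            )
        _check_template(seq, template)
        evaluation = evaluate_ensemble(seq, model, config.backend)
        _, N = ensemble_defect(evaluation.matrices, target)
        pi = 1.0 - equilibrium_probability(seq, target, model, evaluation=evaluation)
        if config.track_trace:
            trace.append(IterationRecord(iteration=it, operator=op, m=m, N=N, pi=pi))
        if N < best_N:
            best_seq, best_N, best_pi, best_eval = seq, N, pi, evaluation
        has_pair = bool(_mutable_pairs(seq, target, template))

    elapsed = time.perf_counter() - t0
    dg = free_energy(best_seq, target, model)
    bf = equilibrium_probability(best_seq, target, model, evaluation=best_eval)
    mu = structure_distance(best_eval.summary.mfe_structure, target)
    return DesignResult(
        sequence=best_seq,
        N=best_N,
        pi=best_pi,
        dG=dg,
        mfe_defect=mu,
        boltzmann_frequency=bf,
        iterations_used=it,
        elapsed_seconds=elapsed,
        reached_fstop=best_N <= config.f_stop,
        seed_sequence=seed_seq,
        seed_N=seed_N,
        trace=tuple(trace),
    )


def run_trials(
    target: PairedStructure,
    template: DesignTemplate | str | None = None,
    config: DesignConfig | None = None,
    trials: int = 30,
) -> list[DesignResult]:
    """Independent seeded design trials.

    Trial k draws from ``default_rng((base_seed, k))`` so every result is
    bit-reproducible from the config alone.
    """
    config = config if config is not None else DesignConfig()
    base = config.rng_seed
    results = []
    for k in range(trials):
        seed = tuple(base) + (k,) if isinstance(base, (tuple, list)) else (base, k)
        rng = np.random.default_rng(seed)
        results.append(design(target, template, config, rng=rng))
    return results
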