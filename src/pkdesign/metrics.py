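"""Sequence-quality measures at equilibrium.

For a sequence phi evaluated against a target structure tau:

* ensemble defect n(phi, tau): expected number of incorrectly paired
  nucleotides at equilibrium, ``n - sum(P * S)`` over the augmented
  matrices; normalized ensemble defect N = n(phi, tau)/n.
* probability defect pi = 1 - p(phi, tau): total probability of all
  non-target structures.
* Boltzmann frequency B_f = exp(-dG/kbt)/Q: the target's share of the
  ensemble.  Algebraically identical to the equilibrium probability;
  the package computes one quantity reported under both names.
* MFE defect mu: per-position structure Hamming distance between the
  predicted MFE structure and the target; mu = 0 defines design success.
* sequence identity S_id: mean pairwise fraction of identical positions
  across a set of designed sequences (lower = more diverse set).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np

from .structures import PairedStructure, structure_matrix
from .thermo import (
    DEFAULT_MODEL,
    EnergyModel,
    EnsembleEvaluation,
    PairProbabilityMatrices,
    equilibrium_probability,
    evaluate_ensemble,
)

__all__ = [
    "ensemble_defect",
    "probability_defect",
    "boltzmann_frequency",
    "mfe_defect",
    "structure_distance",
    "sequence_identity",
]


def ensemble_defect(
    matrices: PairProbabilityMatrices, S: np.ndarray | PairedStructure
) -> tuple[float, float]:
    """Ensemble defect and its normalized value.

    ``n(phi, tau) = n - sum_{i, j<=n+1} P[i, j] * S[i, j]`` counts the
    ensemble-average number of nucleotides whose pairing state disagrees
    with the target; dividing by n gives N in [0, 1].
    """
    if isinstance(S, PairedStructure):
        S = structure_matrix(S)
    n = S.shape[0]
    if matrices.P.shape != S.shape:
        raise ValueError(
            f"matrix shapes differ: P is {matrices.P.shape}, S is {S.shape}"
        )
    defect = float(n - np.sum(matrices.P * S))
    return defect, defect / n


def probability_defect(p: float) -> float:
    """pi = 1 - p: the summed probability of all non-target structures."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return 1.0 - p


def boltzmann_frequency(
    seq: str,
    target: PairedStructure,
    model: EnergyModel = DEFAULT_MODEL,
    backend: str = "exact",
    evaluation: EnsembleEvaluation | None = None,
    **kwargs,
) -> float:
    """B_f = exp(-dG(phi, tau)/kbt)/Q, the target's ensemble share."""
    return equilibrium_probability(seq, target, model, backend, evaluation, **kwargs)


def structure_distance(a: PairedStructure, b: PairedStructure) -> int:
    """Per-position structure Hamming distance.

    A position counts as disagreeing when its pairing partner (or
    unpaired status) differs between the two structures, so paired-to-
    different-partner counts once per endpoint and d = 0 iff the
    structures are identical.
    """
    if a.n != b.n:
        raise ValueError("structures have different lengths")
    pa = a.partner_array()
    pb = b.partner_array()
    return int(np.sum(pa != pb))


def mfe_defect(
    seq: str,
    target: PairedStructure,
    model: EnergyModel = DEFAULT_MODEL,
    backend: str = "exact",
    evaluation: EnsembleEvaluation | None = None,
    **kwargs,
) -> int:
    """mu = d(MFE_phi, tau); a design is successful iff mu = 0."""
    if evaluation is None:
        evaluation = evaluate_ensemble(seq, model, backend, **kwargs)
    return structure_distance(evaluation.summary.mfe_structure, target)


def sequence_identity(seqs: Sequence[str]) -> float:
    """Mean pairwise fraction of identical positions, over unordered
    distinct sequence pairs (gap-free equal-length alignment)."""
    if len(seqs) < 2:
        raise ValueError("sequence identity needs at least 2 sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences have unequal lengths")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), n)
    total = 0.0
    npairs = 0
    for a, b in combinations(range(len(seqs)), 2):
        total += float(np.mean(arr[a] == arr[b]))
        npairs += 1
    return total / npairs
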