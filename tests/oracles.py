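"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: structures are
enumerated by iterating over subsets of candidate pairs, bipartiteness
is checked with networkx, and statistics are recomputed from first
principles, so agreement with the package is informative.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np

ALLOWED = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def candidate_pairs(seq: str) -> list[tuple[int, int]]:
    """All 1-based (i, j) with j >= i+3 whose bases can pair."""
    n = len(seq)
    return [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + 3, n + 1)
        if (seq[i - 1], seq[j - 1]) in ALLOWED
    ]


def crossing_graph(pairs: list[tuple[int, int]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(pairs)))
    for a in range(len(pairs)):
        for b in range(a + 1, len(pairs)):
            (i, j), (k, l) = pairs[a], pairs[b]
            if i < k < j < l or k < i < l < j:
                g.add_edge(a, b)
    return g


def is_matching(pairs: list[tuple[int, int]]) -> bool:
    flat = [x for p in pairs for x in p]
    return len(flat) == len(set(flat))


def brute_force_structures(seq: str, pk_allowed: bool = True) -> list[frozenset[tuple[int, int]]]:
    """Every admissible structure as a frozenset of 1-based pairs.

    Iterates over all subsets of candidate pairs; keeps matchings whose
    crossing graph is empty (pk_allowed=False) or bipartite.
    """
    cands = candidate_pairs(seq)
    out = []
    for r in range(len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            combo = list(combo)
            if not is_matching(combo):
                continue
            g = crossing_graph(combo)
            if not pk_allowed and g.number_of_edges() > 0:
                continue
            if pk_allowed and not nx.is_bipartite(g):
                continue
            out.append(frozenset(combo))
    return out


def canonical_pages(pairs: frozenset[tuple[int, int]]) -> dict[tuple[int, int], int]:
    """Canonical page assignment: 5'-most pair of each crossing-graph
    component takes page 1 (networkx-based, independent of the package)."""
    plist = sorted(pairs)
    g = crossing_graph(plist)
    pages: dict[tuple[int, int], int] = {}
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        anchor = comp[0]  # smallest index == 5'-most pair (plist sorted)
        coloring = nx.bipartite.color(g.subgraph(comp))
        for node in comp:
            same = coloring[node] == coloring[anchor]
            pages[plist[node]] = 1 if same else 2
    return pages


def structure_energy(seq: str, pairs: frozenset[tuple[int, int]], model) -> float:
    energies = dict(model.pair_energies)
    cls = {
        ("A", "U"): "AU", ("U", "A"): "AU",
        ("G", "C"): "GC", ("C", "G"): "GC",
        ("G", "U"): "GU", ("U", "G"): "GU",
    }
    pages = canonical_pages(pairs)
    total = 0.0
    for i, j in pairs:
        total += energies[cls[(seq[i - 1], seq[j - 1])]]
        if pages[(i, j)] == 2:
            total += model.pk_penalty
    g = crossing_graph(sorted(pairs))
    total += model.pk_init * sum(
        1 for comp in nx.connected_components(g) if len(comp) >= 2
    )
    return total


def brute_force_partition(seq: str, model, pk_allowed: bool = True):
    """(Q, per-structure list of (pairs, energy, probability))."""
    structs = brute_force_structures(seq, pk_allowed)
    energies = [structure_energy(seq, s, model) for s in structs]
    weights = [math.exp(-e / model.kbt) for e in energies]
    q = sum(weights)
    return q, [
        (s, e, w / q) for s, e, w in zip(structs, energies, weights)
    ]


def brute_force_pair_matrix(seq: str, model, pk_allowed: bool = True):
    """Augmented P plus page-split P', P'' straight from the definition."""
    n = len(seq)
    q, recs = brute_force_partition(seq, model, pk_allowed)
    P = np.zeros((n, n + 1))
    P1 = np.zeros((n, n))
    P2 = np.zeros((n, n))
    for pairs, _e, p in recs:
        pages = canonical_pages(pairs)
        paired = set()
        for i, j in pairs:
            P[i - 1, j - 1] += p
            P[j - 1, i - 1] += p
            tgt = P1 if pages[(i, j)] == 1 else P2
            tgt[i - 1, j - 1] += p
            tgt[j - 1, i - 1] += p
            paired.update((i, j))
        for i in range(1, n + 1):
            if i not in paired:
                P[i - 1, n] += p
    return P, P1, P2


def direct_ensemble_defect(seq: str, target_pairs: frozenset, n: int, model) -> float:
    """Ensemble average of the per-structure count of incorrectly paired
    nucleotides, by definition (no matrices)."""
    def partner_map(pairs):
        m = {}
        for i, j in pairs:
            m[i] = j
            m[j] = i
        return m

    tgt = partner_map(target_pairs)
    _q, recs = brute_force_partition(seq, model, pk_allowed=True)
    total = 0.0
    for pairs, _e, p in recs:
        cur = partner_map(pairs)
        wrong = sum(1 for i in range(1, n + 1) if cur.get(i) != tgt.get(i))
        total += p * wrong
    return total


def sign_test_pvalue(wins: int, trials: int) -> float:
    """Two-sided exact sign test by binomial tail sums (Fractions)."""
    if trials == 0:
        return 1.0
    def tail(k_extreme_hi):
        return sum(
            Fraction(math.comb(trials, k), 2**trials) for k in range(k_extreme_hi, trials + 1)
        )
    k = wins
    lo = sum(Fraction(math.comb(trials, t), 2**trials) for t in range(0, k + 1))
    hi = tail(k)
    return float(min(1, 2 * min(lo, hi)))
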