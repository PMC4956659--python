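"""Synthetic targets and sequences for testing and benchmarking.

Real pseudoknot design benchmarks draw on curated natural structures
(H-type pseudoknots dominate those collections).  This module generates
structurally similar synthetic targets at desk scale, so every other
module is testable without any download: a nested helix whose loop
hosts the 5' half of a second helix closing downstream of the first —
every page-2 pair genuinely crosses page-1 pairs.

The ``toy`` suite bundles hand-built cases including an 85-nt
hammerhead-ribozyme target with its conserved-motif design template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampler import initialize_seed
from .structures import (
    DesignTemplate,
    PairedStructure,
    parse_dot_bracket,
    validate_template,
)

__all__ = [
    "SyntheticTargetSpec",
    "random_two_page_structure",
    "random_sequence_for",
    "suite",
    "HAMMERHEAD_DOTBRACKET",
    "HAMMERHEAD_TEMPLATE",
]


# An 85-nt cis-acting hammerhead ribozyme target.  SYNTHETIC
# RECONSTRUCTION: the published secondary-structure string for this
# ribozyme is typeset with ellipses, so exact loop lengths are ambiguous;
# this layout preserves the printed stem/pseudoknot skeleton (5-pair
# pseudoknot helix opening at position 3 inside stem 1) and places the
# conserved catalytic motifs consistently with the 85-character template.
HAMMERHEAD_DOTBRACKET = (
    ".."            # 1-2
    "[[[[["         # 3-7    pseudoknot helix, 5' half
    "...."          # 8-11
    "((((("         # 12-16  stem 1, 5' half
    "........."     # 17-25  conserved CCUGAUGAG, unpaired
    "((("           # 26-28  stem 2, 5' half
    ".."            # 29-30
    "]]]]]"         # 31-35  pseudoknot helix, 3' half
    "..........."   # 36-46  loop holding conserved GCGAAA
    ")))"           # 47-49  stem 2, 3' half
    ".."            # 50-51
    "((((((("       # 52-58  stem 3, 5' half
    "......"        # 59-64
    ")))))))"       # 65-71  stem 3, 3' half (UCG motif on 69-71)
    "."             # 72
    ")))))"         # 73-77  stem 1, 3' half
    "........"      # 78-85
)

#: Conserved-motif design template: CCUGAUGAG (17-25), GCGAAA (41-46),
#: UCG (69-71); every other position free.
HAMMERHEAD_TEMPLATE = "o" * 16 + "CCUGAUGAG" + "o" * 15 + "GCGAAA" + "o" * 22 + "UCG" + "o" * 14


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Shape of one synthetic two-page target."""

    n: int
    num_nested_pairs: int
    num_pk_pairs: int
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if 2 * (self.num_nested_pairs + self.num_pk_pairs) > self.n:
            raise ValueError("more paired positions requested than sequence length")
        if self.num_pk_pairs > 0 and self.num_nested_pairs == 0:
            raise ValueError("pseudoknot pairs need nested pairs to cross")


def random_two_page_structure(spec: SyntheticTargetSpec) -> PairedStructure:
    """Random H-type-like target with the requested pair counts.

    Layout: gap, nested helix open, gap, pk helix open, gap, nested
    helix close, gap, pk helix close, gap — so each page-2 pair crosses
    every page-1 pair.  Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h1, h2, n = spec.num_nested_pairs, spec.num_pk_pairs, spec.n
    slack = n - 2 * (h1 + h2)
    if h2 == 0:
        # hairpin: g0 (((( g1 )))) g2, hairpin loop g1 >= 2
        if h1 == 0:
            return parse_dot_bracket("." * n)
        if slack < 2:
            raise ValueError(f"spec infeasible: need >= 2 unpaired loop bases, have {slack}")
        mins = np.array([0, 2, 0])
        extra = rng.multinomial(slack - mins.sum(), [1 / 3] * 3)
        g0, g1, g2 = (mins + extra).tolist()
        db = "." * g0 + "(" * h1 + "." * g1 + ")" * h1 + "." * g2
        return parse_dot_bracket(db)
    # pseudoknotted: g0 ( g1 [ g2 ) g3 ] g4
    min_g1 = max(0, 2 - h2)  # innermost nested pair spans g1 + h2 + g2
    min_g3 = max(0, 2 - h1)  # innermost pk pair spans g2 + h1 + g3
    if slack < min_g1 + min_g3:
        raise ValueError("spec infeasible: not enough unpaired positions for loops")
    mins = np.array([0, min_g1, 0, min_g3, 0])
    extra = rng.multinomial(slack - mins.sum(), [1 / 5] * 5)
    g0, g1, g2, g3, g4 = (mins + extra).tolist()
    db = (
        "." * g0 + "(" * h1 + "." * g1 + "[" * h2 + "." * g2
        + ")" * h1 + "." * g3 + "]" * h2 + "." * g4
    )
    return parse_dot_bracket(db)


def random_sequence_for(
    structure: PairedStructure,
    gc_content: float = 0.5,
    rng: np.random.Generator | None = None,
) -> str:
    """Pair-compatible random sequence at roughly the requested GC fraction.

    Reuses seed initialization with an all-open template.
    """
    return initialize_seed(structure, None, gc_content, rng)


def _toy_suite() -> list[tuple[str, PairedStructure, DesignTemplate | None]]:
    hh = parse_dot_bracket(HAMMERHEAD_DOTBRACKET)
    return [
        ("hairpin", parse_dot_bracket("(((...)))"), None),
        ("htype", parse_dot_bracket("((..[[..))..]]"), None),
        ("two-helix", parse_dot_bracket("((((...)))).((...)).."), None),
        ("hammerhead", hh, validate_template(HAMMERHEAD_TEMPLATE, hh)),
    ]


def _generated_suite(
    prefix: str, count: int, lengths: tuple[int, int], seed_base: int
) -> list[tuple[str, PairedStructure, DesignTemplate | None]]:
    lo, hi = lengths
    out = []
    for k in range(count):
        rng = np.random.default_rng((seed_base, k))
        n = int(rng.integers(lo, hi + 1))
        h1 = int(rng.integers(3, max(4, n // 5) + 1))
        h2 = int(rng.integers(2, 4))
        while 2 * (h1 + h2) > n - 4:
            h1 -= 1
        spec = SyntheticTargetSpec(
            n=n, num_nested_pairs=h1, num_pk_pairs=h2, rng_seed=int(rng.integers(2**31))
        )
        out.append((f"{prefix}-{k + 1:02d}", random_two_page_structure(spec), None))
    return out


def suite(name: str) -> list[tuple[str, PairedStructure, DesignTemplate | None]]:
    """Reproducible named fixture sets.

    ``toy``
        Hand-built cases, including the 85-nt hammerhead target with
        its conserved-motif template.
    ``desk``
        20 two-page targets of length 15-16 nt, sized so the exhaustive
        two-page ensemble of any candidate stays enumerable (a few
        milliseconds per evaluation) inside a full design loop.
    ``bench``
        20 two-page targets of length 21-35 nt, the shape of curated
        pseudoknot benchmark sets at reduced length; suitable for the
        nested backend or structure-level operations, not for exact
        full-ensemble design loops.
    """
    if name == "toy":
        return _toy_suite()
    if name == "desk":
        return _generated_suite("desk", 20, (15, 16), seed_base=20151)
    if name == "bench":
        return _generated_suite("plike", 20, (21, 35), seed_base=20152)
    raise ValueError(f"unknown suite {name!r}; choose toy, desk or bench")
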