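"""Pseudoknotted secondary structures, design templates, and their validation.

A secondary structure is a partial matching on sequence positions: every
position pairs with at most one partner, and any pair (i, j) must satisfy
j >= i + 3 (at least two unpaired bases inside a hairpin loop).  The
structures handled here belong to the *two-page* class: the pairs can be
split into two groups ("pages") such that pairs within a group never cross.
Page 1 is written with round brackets, page 2 (the pseudoknot pairs that
cross page-1 pairs) with square brackets, unpaired positions with dots.

All user-facing coordinates are 1-based, matching the usual convention in
the RNA structure literature.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ALLOWED_PAIRS",
    "RNA_ALPHABET",
    "StructureError",
    "StructureClassError",
    "TemplateError",
    "PairedStructure",
    "DesignTemplate",
    "parse_dot_bracket",
    "write_dot_bracket",
    "two_page_split",
    "structure_matrix",
    "validate_template",
    "validate_sequence",
    "is_compatible",
    "pairs_cross",
]

RNA_ALPHABET = ("A", "C", "G", "U")

#: The six canonical base pairs (Watson-Crick plus the G-U wobble).
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: For a given base, the bases it may pair with.
PARTNERS: Mapping[str, tuple[str, ...]] = {
    "A": ("U",),
    "U": ("A", "G"),
    "G": ("C", "U"),
    "C": ("G",),
}

MIN_LOOP_SPAN = 3  # a pair (i, j) requires j >= i + MIN_LOOP_SPAN


class StructureError(ValueError):
    """Raised for malformed structures or dot-bracket strings."""


class StructureClassError(StructureError):
    """Raised when a pair set lies outside the supported two-page class.

    Mirrors the dataset filter of the benchmark protocol: targets whose
    crossing graph is not bipartite cannot be decomposed into two
    pseudoknot-free structures and are rejected.
    """


class TemplateError(ValueError):
    """Raised for invalid design templates."""


def pairs_cross(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True iff base pairs *p* and *q* cross (interleave)."""
    i, j = p
    k, l = q
    return (i < k < j < l) or (k < i < l < j)


@dataclass(frozen=True)
class PairedStructure:
    """A target secondary structure over ``n`` nucleotides.

    Attributes
    ----------
    n:
        Sequence length.
    pairs:
        Frozen set of 1-based ``(i, j)`` pairs with ``i < j``.
    page:
        Mapping of each pair to page 1 (round brackets) or 2 (square).
    dotbracket:
        The dot-bracket text; writing a parsed structure reproduces its
        input exactly.
    """

    n: int
    pairs: frozenset[tuple[int, int]]
    page: Mapping[tuple[int, int], int]
    dotbracket: str = field(default="")

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise StructureError("structure length must be positive")
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise StructureError(f"pair ({i},{j}) out of range for n={self.n}")
            if j < i + MIN_LOOP_SPAN:
                raise StructureError(
                    f"pair ({i},{j}) violates the minimum hairpin loop (j >= i+{MIN_LOOP_SPAN})"
                )
            if i in seen or j in seen:
                raise StructureError(f"position in pair ({i},{j}) paired more than once")
            seen.add(i)
            seen.add(j)
        for pr in self.pairs:
            if pr not in self.page:
                raise StructureError(f"pair {pr} has no page assignment")
        for pg in (1, 2):
            same = [p for p in self.pairs if self.page[p] == pg]
            for a in range(len(same)):
                for b in range(a + 1, len(same)):
                    if pairs_cross(same[a], same[b]):
                        raise StructureClassError(
                            f"pairs {same[a]} and {same[b]} cross within page {pg}"
                        )
        if not self.dotbracket:
            object.__setattr__(self, "dotbracket", write_dot_bracket(self))
        elif len(self.dotbracket) != self.n:
            raise StructureError("dotbracket length does not match n")

    # -- convenience accessors -------------------------------------------------

    def partner_array(self) -> np.ndarray:
        """0-based partner index per position; -1 for unpaired."""
        partner = np.full(self.n, -1, dtype=np.int64)
        for i, j in self.pairs:
            partner[i - 1] = j - 1
            partner[j - 1] = i - 1
        return partner

    def partner_of(self, i: int) -> int | None:
        """1-based partner of 1-based position *i*, or None if unpaired."""
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    @property
    def unpaired_positions(self) -> tuple[int, ...]:
        paired = {k for p in self.pairs for k in p}
        return tuple(i for i in range(1, self.n + 1) if i not in paired)

    @property
    def has_pseudoknot(self) -> bool:
        return any(pg == 2 for pg in self.page.values())

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)


def parse_dot_bracket(text: str) -> PairedStructure:
    """Parse a two-layer dot-bracket string into a :class:`PairedStructure`.

    Round brackets encode page-1 pairs, square brackets page-2 pairs.
    Additional bracket layers (``{}``, letters) are rejected: the supported
    structure class is exactly the one decomposable into two
    pseudoknot-free pages.
    """
    if not text:
        raise StructureError("empty dot-bracket string")
    stacks: dict[str, list[int]] = {"(": [], "[": []}
    closing = {")": "(", "]": "["}
    pairs: set[tuple[int, int]] = set()
    page: dict[tuple[int, int], int] = {}
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in stacks:
            stacks[ch].append(pos)
        elif ch in closing:
            stack = stacks[closing[ch]]
            if not stack:
                raise StructureError(f"unbalanced '{ch}' at position {pos}")
            i = stack.pop()
            if pos < i + MIN_LOOP_SPAN:
                raise StructureError(
                    f"pair ({i},{pos}) violates the minimum hairpin loop "
                    f"(j >= i+{MIN_LOOP_SPAN})"
                )
            pr = (i, pos)
            pairs.add(pr)
            page[pr] = 1 if ch == ")" else 2
        else:
            raise StructureError(f"illegal character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureError(f"unbalanced '{opener}' at position {stack[-1]}")
    return PairedStructure(n=len(text), pairs=frozenset(pairs), page=page, dotbracket=text)


def write_dot_bracket(structure: PairedStructure) -> str:
    """Render a structure as dot-bracket text (inverse of :func:`parse_dot_bracket`)."""
    chars = ["."] * structure.n
    for (i, j), pg in structure.page.items():
        op, cl = ("(", ")") if pg == 1 else ("[", "]")
        chars[i - 1] = op
        chars[j - 1] = cl
    return "".join(chars)


def two_page_split(pairs: Iterable[tuple[int, int]], n: int) -> dict[tuple[int, int], int]:
    """Deterministically 2-color the crossing graph of a pair set.

    Two pairs (i, j), (k, l) cross iff i < k < j < l.  Each color class
    ("page") must be internally non-crossing, which is exactly a proper
    2-coloring of the crossing graph; a structure is accepted iff that
    graph is bipartite.  Within each connected component the 5'-most pair
    (lexicographically smallest) receives page 1 and the assignment is
    propagated by breadth-first search, so the result is deterministic.

    Raises :class:`StructureClassError` on a non-bipartite crossing graph
    and :class:`StructureError` on invalid pair sets.
    """
    plist = sorted(set(tuple(p) for p in pairs))
    seen: set[int] = set()
    for i, j in plist:
        if not (1 <= i < j <= n):
            raise StructureError(f"pair ({i},{j}) out of range for n={n}")
        if j < i + MIN_LOOP_SPAN:
            raise StructureError(
                f"pair ({i},{j}) violates the minimum hairpin loop (j >= i+{MIN_LOOP_SPAN})"
            )
        if i in seen or j in seen:
            raise StructureError(f"position in pair ({i},{j}) paired more than once")
        seen.add(i)
        seen.add(j)

    m = len(plist)
    adj: list[list[int]] = [[] for _ in range(m)]
    for a in range(m):
        for b in range(a + 1, m):
            if pairs_cross(plist[a], plist[b]):
                adj[a].append(b)
                adj[b].append(a)

    color = [-1] * m
    for start in range(m):  # plist is sorted: the first unseen pair is 5'-most
        if color[start] != -1:
            continue
        color[start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if color[v] == -1:
                    color[v] = color[u] ^ 1
                    queue.append(v)
                elif color[v] == color[u]:
                    raise StructureClassError(
                        "crossing graph is not bipartite: structure is outside "
                        "the supported two-page pseudoknot class"
                    )
    return {plist[k]: color[k] + 1 for k in range(m)}


def from_pairs(pairs: Iterable[tuple[int, int]], n: int) -> PairedStructure:
    """Build a structure from a bare pair list, assigning pages canonically."""
    page = two_page_split(pairs, n)
    return PairedStructure(n=n, pairs=frozenset(page), page=page)


def structure_matrix(structure: PairedStructure) -> np.ndarray:
    """The augmented n x (n+1) 0/1 structure matrix S(tau).

    ``S[i, j] = 1`` iff positions i+1 and j+1 are paired; the extra last
    column flags unpaired positions, so every row sums to exactly 1.
    """
    n = structure.n
    S = np.zeros((n, n + 1), dtype=np.int8)
    for i, j in structure.pairs:
        S[i - 1, j - 1] = 1
        S[j - 1, i - 1] = 1
    for i in structure.unpaired_positions:
        S[i - 1, n] = 1
    return S


@dataclass(frozen=True)
class DesignTemplate:
    """Per-position constraint string over {A, C, G, U, o}.

    Non-'o' positions are copied into the seed sequence and are immune to
    mutation throughout a design run.
    """

    text: str

    @property
    def n(self) -> int:
        return len(self.text)

    def is_locked(self, i: int) -> bool:
        """True iff 1-based position *i* is constrained."""
        return self.text[i - 1] != "o"

    @property
    def locked_positions(self) -> tuple[int, ...]:
        return tuple(i for i in range(1, self.n + 1) if self.is_locked(i))

    @classmethod
    def all_open(cls, n: int) -> "DesignTemplate":
        return cls("o" * n)


def validate_template(template: str | DesignTemplate, target: PairedStructure) -> DesignTemplate:
    """Check a template against its target structure.

    Verifies length, alphabet, and that any pair whose two ends are both
    locked is constrained to one of the six allowed base pairs.
    """
    text = template.text if isinstance(template, DesignTemplate) else template
    if len(text) != target.n:
        raise TemplateError(
            f"template length {len(text)} does not match target length {target.n}"
        )
    for pos, ch in enumerate(text, start=1):
        if ch not in ("A", "C", "G", "U", "o"):
            raise TemplateError(f"illegal template character {ch!r} at position {pos}")
    for i, j in target.pairs:
        bi, bj = text[i - 1], text[j - 1]
        if bi != "o" and bj != "o" and (bi, bj) not in ALLOWED_PAIRS:
            raise TemplateError(
                f"template locks pair ({i},{j}) to {bi}-{bj}, which is not an allowed base pair"
            )
    return DesignTemplate(text)


def validate_sequence(seq: str, n: int | None = None) -> str:
    """Validate an RNA sequence string (alphabet {A, C, G, U}).

    DNA letter T is rejected rather than converted: silent conversion
    hides input errors.
    """
    if not seq:
        raise ValueError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in RNA_ALPHABET:
            raise ValueError(f"illegal base {ch!r} at position {pos}")
    if n is not None and len(seq) != n:
        raise ValueError(f"sequence length {len(seq)} does not match expected {n}")
    return seq


def is_compatible(seq: str, structure: PairedStructure) -> bool:
    """True iff every target pair's bases form one of the six allowed pairs."""
    validate_sequence(seq, structure.n)
    return all((seq[i - 1], seq[j - 1]) in ALLOWED_PAIRS for i, j in structure.pairs)
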