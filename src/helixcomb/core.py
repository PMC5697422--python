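"""Sequence model, base-pairing rules, and secondary-structure representation.

An RNA secondary structure is modelled as a set of base pairs ``(i, j)``
(0-based, ``i < j``) that is *nested*: no two pairs cross, and no index is
used twice.  Pairing follows Watson-Crick (A-U, C-G) plus the G-U wobble.
Structures are rendered and parsed in Vienna dot-bracket notation
(``.`` unpaired, one level of ``(`` / ``)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Tuple

import numpy as np

RESIDUES = frozenset("ACGU")

#: Unordered residue pairs that may form a base pair (Watson-Crick + wobble).
PAIRABLE = frozenset({frozenset("AU"), frozenset("CG"), frozenset("GU")})

#: Watson-Crick pairs only (no wobble); used by the motif matcher's ``W``.
WATSON_CRICK = frozenset({frozenset("AU"), frozenset("CG")})


class InvalidSequenceError(ValueError):
    """A residue outside {A, C, G, U} after normalization."""


class StructureError(ValueError):
    """A pair set that is not a valid nested secondary structure."""


def normalize_residues(raw: str) -> str:
    """Uppercase the input and map T (DNA alphabet) to U.

    Any other symbol is a hard error; IUPAC ambiguity codes are rejected
    because the pair table is defined only over A/C/G/U.
    """
    out = raw.upper().replace("T", "U")
    for pos, ch in enumerate(out):
        if ch not in RESIDUES:
            raise InvalidSequenceError(
                f"illegal residue {raw[pos]!r} at position {pos + 1} (1-based)"
            )
    return out


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with an identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))
        if self.n < 1:
            raise InvalidSequenceError("empty sequence")

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> str:
        return self.residues[i]


def can_pair(a: str, b: str) -> bool:
    """True iff residues *a* and *b* form a Watson-Crick or wobble pair."""
    if a not in RESIDUES or b not in RESIDUES:
        raise InvalidSequenceError(f"non-residue symbol in pair ({a!r}, {b!r})")
    return (frozenset((a, b)) if a != b else frozenset((a,))) in PAIRABLE


def is_watson_crick(a: str, b: str) -> bool:
    """True iff *a*-*b* is A-U or C-G (wobble G-U excluded)."""
    if a not in RESIDUES or b not in RESIDUES:
        raise InvalidSequenceError(f"non-residue symbol in pair ({a!r}, {b!r})")
    return (frozenset((a, b)) if a != b else frozenset((a,))) in WATSON_CRICK


class PairTable:
    """Upper-triangular lookup of pairability for every ordered index pair.

    ``pairable(i, j)`` for ``0 <= i < j < n`` depends only on the residues at
    the two positions.  Stored as a boolean matrix; only the upper triangle
    is meaningful.
    """

    def __init__(self, seq: RnaSequence):
        self.n = seq.n
        codes = np.frombuffer(seq.residues.encode(), dtype=np.uint8)
        # vectorised pairwise test: complement sums are unique for the three
        # allowed pairs (A+U, C+G, G+U) over the ASCII codes A=65 C=67 G=71 U=85
        s = codes[:, None].astype(np.int16) + codes[None, :]
        mat = (s == ord("A") + ord("U")) | (s == ord("C") + ord("G")) | (s == ord("G") + ord("U"))
        mat &= np.triu(np.ones((self.n, self.n), dtype=bool), k=1)
        self._mat = mat

    def pairable(self, i: int, j: int) -> bool:
        if not (0 <= i < j < self.n):
            raise IndexError(f"pair indices ({i}, {j}) out of range for n={self.n}")
        return bool(self._mat[i, j])

    __call__ = pairable


@dataclass(frozen=True)
class FoldParams:
    """Enumeration parameters.

    L
        Minimum helix length in base pairs.  ``L = 2`` removes lonely
        (isolated, unstacked) pairs; ``L = 1`` allows them.
    hp
        Minimum hairpin loop length in nucleotides (default 3: an RNA needs
        at least 3 unpaired nucleotides to fold back on itself).
    bundling
        Group similar helices into bundles and enumerate over
        representatives only.
    forced_unpaired
        0-based positions that may not pair (e.g. chemically modified
        nucleotides that block Watson-Crick pairing).
    min_helix_count / min_helix_len_filter
        Optional output filter: keep only structures with at least
        ``min_helix_count`` maximal helices of length
        ``>= min_helix_len_filter``.
    """

    L: int = 2
    hp: int = 3
    bundling: bool = False
    forced_unpaired: FrozenSet[int] = frozenset()
    min_helix_count: int = 0
    min_helix_len_filter: int = 1

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("minimum helix length L must be >= 1")
        if self.hp < 0:
            raise ValueError("minimum hairpin length hp must be >= 0")
        if self.min_helix_count < 0 or self.min_helix_len_filter < 0:
            raise ValueError("structure filters must be non-negative")
        object.__setattr__(self, "forced_unpaired", frozenset(self.forced_unpaired))

    def with_forced_unpaired(self, positions: Iterable[int]) -> "FoldParams":
        return replace(self, forced_unpaired=frozenset(positions))


Pair = Tuple[int, int]


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested set of base pairs.

    The constructor validates nestedness and single pairing; the hairpin
    constraint is a property of the enumeration parameters, checked by
    :func:`satisfies_hairpin`.
    """

    pairs: FrozenSet[Pair] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        seen = set()
        for i, j in pairs:
            if i >= j:
                raise StructureError(f"pair ({i}, {j}) must have i < j")
            if i in seen or j in seen:
                raise StructureError(f"index used in more than one pair: ({i}, {j})")
            seen.add(i)
            seen.add(j)
        ordered = sorted(pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k > j:
                    break
                if k > i and not (l < j):  # i < k <= j requires l < j for nesting
                    raise StructureError(
                        f"crossing pairs ({i}, {j}) and ({k}, {l}) (pseudoknot)"
                    )

    def __len__(self) -> int:
        return len(self.pairs)

    def partner_array(self, n: int) -> list:
        """Partner index per position (``-1`` when unpaired)."""
        partner = [-1] * n
        for i, j in self.pairs:
            if j >= n:
                raise StructureError(f"pair ({i}, {j}) out of range for n={n}")
            partner[i] = j
            partner[j] = i
        return partner

    def satisfies_hairpin(self, hp: int) -> bool:
        return all(j - i - 1 >= hp for i, j in self.pairs)


OPEN_CHAIN = SecondaryStructure(frozenset())


def to_dot_bracket(s: SecondaryStructure, n: int) -> str:
    """Render *s* as a dot-bracket string of length *n*."""
    out = ["."] * n
    for i, j in s.pairs:
        if not (0 <= i < j < n):
            raise StructureError(f"pair ({i}, {j}) out of range for n={n}")
        out[i] = "("
        out[j] = ")"
    return "".join(out)


def parse_dot_bracket(text: str) -> SecondaryStructure:
    """Parse Vienna dot-bracket text (inverse of :func:`to_dot_bracket`)."""
    stack = []
    pairs = set()
    for pos, ch in enumerate(text):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos + 1}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"illegal symbol {ch!r} at position {pos + 1}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
    return SecondaryStructure(frozenset(pairs))


def maximal_stacks(s: SecondaryStructure) -> list:
    """Lengths of maximal runs of consecutively stacked pairs.

    Pairs ``(i, j)`` and ``(i+1, j-1)`` stack; a maximal run is one that
    cannot be extended by another stacked pair of the structure.
    """
    pairs = set(s.pairs)
    lengths = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pairs:
            continue  # not the outer end of a run
        length = 1
        while (i + length, j - length) in pairs:
            length += 1
        lengths.append(length)
    return lengths
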