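"""Helix components: the combinatorial building blocks of enumeration.

A *component* is a contiguous stack of base pairs keyed by its 5' start
position (its "type"), with length capped at ``2L - 1``: any longer stack
can be tiled from shorter components, so storing longer ones would create
duplicate routes to the same structure.  A maximal stack of total length
``a`` has exactly one canonical tiling ``a = (q - 1) * L + (L + k)`` with
``0 <= k < L``: outer pieces of length exactly ``L``, one innermost piece
of length ``L + k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence

from .core import FoldParams, PairTable, RnaSequence


@dataclass(frozen=True, order=True)
class Helix:
    """A contiguous stack of ``length`` pairs with outer pair ``(i, j)``.

    The pairs are ``(i + t, j - t)`` for ``0 <= t < length``.
    """

    i: int
    j: int
    length: int

    @property
    def inner_i(self) -> int:
        return self.i + self.length - 1

    @property
    def inner_j(self) -> int:
        return self.j - self.length + 1

    @property
    def span(self) -> int:
        """Extent in nucleotides from 5' outer edge to 3' outer edge."""
        return self.j - self.i + 1

    @property
    def gap(self) -> int:
        """Unpaired stretch enclosed by the innermost pair."""
        return self.inner_j - self.inner_i - 1

    def pairs(self) -> Iterator:
        for t in range(self.length):
            yield (self.i + t, self.j - t)

    def indices(self) -> Iterator[int]:
        for t in range(self.length):
            yield self.i + t
            yield self.j - t


class ComponentArray:
    """All admissible helices, grouped by 5' start position.

    Within a start, helices are ordered by increasing 3' end then
    increasing length, so output is deterministic and parallel splits are
    stable.
    """

    def __init__(
        self,
        n: int,
        by_start: Dict[int, List[Helix]],
        seq: Optional[RnaSequence] = None,
        pt: Optional[PairTable] = None,
    ):
        self.n = n
        self.seq = seq
        self.pt = pt
        self.by_start: List[List[Helix]] = [[] for _ in range(n)]
        for i, helices in by_start.items():
            self.by_start[i] = sorted(helices, key=lambda h: (h.j, h.length))

    def __iter__(self) -> Iterator[Helix]:
        for cell in self.by_start:
            yield from cell

    def __len__(self) -> int:
        return sum(len(cell) for cell in self.by_start)

    def at(self, i: int) -> Sequence[Helix]:
        return self.by_start[i]

    def dump_tsv(self) -> str:
        """Debug dump: one component per line, 1-based coordinates."""
        lines = ["start\tend\tlength"]
        for h in self:
            lines.append(f"{h.i + 1}\t{h.j + 1}\t{h.length}")
        return "\n".join(lines) + "\n"


def build_component_list(
    seq: RnaSequence, pt: PairTable, params: FoldParams
) -> ComponentArray:
    """Enumerate every qualified helix of length ``L .. 2L - 1``.

    A qualified helix is a contiguous run of pairable stacked pairs whose
    inner gap is at least ``hp`` and that touches no forced-unpaired
    position.  Sub-runs of longer maximal runs are included: the enumerator
    assembles long stacks from adjacent components, so it needs them.
    """
    n = seq.n
    L, hp = params.L, params.hp
    blocked = params.forced_unpaired
    by_start: Dict[int, List[Helix]] = {}
    max_len = 2 * L - 1
    for i in range(n):
        if i in blocked:
            continue
        # j is the 3' outer end; stack grows inward from (i, j)
        for j in range(i + 2 * L + hp - 1, n):
            if j in blocked:
                continue
            if not pt.pairable(i, j):
                continue
            # extend the stack inward as far as pairing and constraints allow
            run = 1
            while run < max_len:
                ii, jj = i + run, j - run
                if ii in blocked or jj in blocked:
                    break
                if jj - ii - 1 < hp or not pt.pairable(ii, jj):
                    break
                run += 1
            for length in range(L, run + 1):
                if (j - length + 1) - (i + length - 1) - 1 < hp:
                    continue
                by_start.setdefault(i, []).append(Helix(i, j, length))
    return ComponentArray(n, by_start, seq=seq, pt=pt)


def decompose_helix_length(a: int, L: int) -> List[int]:
    """Canonical tiling of a stack of total length *a* into component pieces.

    ``a = (q - 1) * L + (L + k)`` with ``0 <= k < L``: ``q - 1`` outer
    pieces of length ``L`` followed (inward) by one piece of length
    ``L + k``.  Every piece lies in ``[L, 2L - 1]`` and the decomposition
    is the unique one the enumerator generates.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if a < L:
        raise ValueError(f"stack length {a} shorter than minimum helix length {L}")
    q, k = divmod(a, L)
    return [L] * (q - 1) + [L + k]


class IntervalLookup:
    """For each position, the nearest position at or after it with components.

    Lets interval scans skip empty component cells; it never changes the
    enumeration output, only the cost.
    """

    NONE = -1

    def __init__(self, ca: ComponentArray):
        self.n = ca.n
        nxt = [self.NONE] * ca.n
        last = self.NONE
        for i in range(ca.n - 1, -1, -1):
            if ca.by_start[i]:
                last = i
            nxt[i] = last
        self._next = nxt

    def next_occupied(self, i: int) -> Optional[int]:
        """Smallest occupied position >= i, or None."""
        if i >= self.n:
            return None
        v = self._next[max(i, 0)]
        return None if v == self.NONE else v


def build_interval_lookup(ca: ComponentArray) -> IntervalLookup:
    return IntervalLookup(ca)
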