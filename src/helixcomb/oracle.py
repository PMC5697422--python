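"""Brute-force reference enumerator for small sequences.

Enumerates nested pair sets by the classic sweep — position ``i`` is either
unpaired or paired with each admissible ``j`` — and filters afterwards on
the maximal-stack criterion.  Deliberately structured nothing like the
component-based jump tree, so the two are unlikely to share bugs; this is
the ground truth every other module is tested against.  Exponential cost:
refuses sequences longer than a configurable cap.
"""

from __future__ import annotations

from typing import Iterable, Set

from .core import (
    FoldParams,
    PairTable,
    RnaSequence,
    SecondaryStructure,
    maximal_stacks,
)

DEFAULT_CAP = 25


def oracle_enumerate(
    seq: RnaSequence,
    L: int = 2,
    hp: int = 3,
    forced_unpaired: Iterable[int] = (),
    cap: int = DEFAULT_CAP,
) -> Set[SecondaryStructure]:
    """All nested structures with hairpin >= hp and maximal stacks >= L.

    Membership is decided per structure, independent of any component
    machinery.  The open (fully unpaired) chain is included.
    """
    if seq.n > cap:
        raise ValueError(
            f"oracle refuses n={seq.n} > cap={cap}: cost is exponential"
        )
    pt = PairTable(seq)
    blocked = frozenset(forced_unpaired)
    n = seq.n

    memo = {}

    def sweep(lo: int, hi: int) -> list:
        """All nested pair sets on [lo, hi] (hairpin-constrained)."""
        if lo >= hi:
            return [frozenset()]
        key = (lo, hi)
        if key in memo:
            return memo[key]
        out = []
        for rest in sweep(lo + 1, hi):
            out.append(rest)  # lo unpaired
        if lo not in blocked:
            for j in range(lo + hp + 1, hi + 1):
                if j in blocked or not pt.pairable(lo, j):
                    continue
                for inner in sweep(lo + 1, j - 1):
                    for rest in sweep(j + 1, hi):
                        out.append(frozenset({(lo, j)}) | inner | rest)
        memo[key] = out
        return out

    structures = set()
    for pairs in sweep(0, n - 1):
        s = SecondaryStructure(pairs)
        if all(length >= L for length in maximal_stacks(s)):
            structures.add(s)
    return structures


def oracle_count(
    seq: RnaSequence, params: FoldParams, cap: int = DEFAULT_CAP
) -> int:
    """Convenience: the size of the oracle set under *params* (no bundling)."""
    return len(
        oracle_enumerate(
            seq,
            L=params.L,
            hp=params.hp,
            forced_unpaired=params.forced_unpaired,
            cap=cap,
        )
    )
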