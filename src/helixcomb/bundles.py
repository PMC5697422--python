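"""Bundling of similar helices.

Helices anchored at a common outer pair within a short sequence window are
*similar*: they are mutually exclusive alternatives or nested elaborations
of one another, never independent structural elements.  A bundle abstracts
all alternatives anchored at one outer pair ``(i, j)`` behind a single
*representative* helix — the maximally saturated stack at that anchor
(largest span, then most stacked pairs).  Enumeration with bundling places
representatives and never descends into a bundled window, which collapses
all interior alternatives into one counted structure; :func:`unbundle`
expands each bundled structure back into the alternatives it stands for,
restoring the complete unbundled ensemble.

Two windows appear here.  ``bundling_window`` (``4L + 2hp - 1``) is the
classical similarity bound: one nucleotide short of the minimum span that
could hold two side-by-side minimal helices.  The extent threshold actually
used to decide which anchors are bundled is wider, ``6L + 2hp - 1`` — one
short of the span that fits a minimal helix next to a two-component stack —
which is the bound consistent with anchored-alternative bundling (see
:func:`bundle_extent_window`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

from .components import ComponentArray, Helix
from .core import FoldParams, SecondaryStructure, StructureError


def bundling_window(L: int, hp: int) -> int:
    """Similarity window ``4L + 2hp - 1``.

    ``4L + 2hp`` is the minimum span that fits two adjacent minimal
    helices, so a window one nucleotide shorter can never hold a
    multibranch loop of two minimal stems.
    """
    if L < 1 or hp < 0:
        raise ValueError("L must be >= 1 and hp >= 0")
    return 4 * L + 2 * hp - 1


def bundle_extent_window(L: int, hp: int) -> int:
    """Extent threshold ``6L + 2hp - 1`` below which an anchor is bundled.

    A helix whose outer pair spans at most this many nucleotides is
    abstracted into its bundle's representative.  This is one nucleotide
    short of ``6L + 2hp``, the minimum span holding a minimal helix
    side-by-side with a two-component (length ``2L``) stack, i.e. the
    widest window whose alternatives are still dominated by a single
    saturated anchor stack.
    """
    if L < 1 or hp < 0:
        raise ValueError("L must be >= 1 and hp >= 0")
    return 6 * L + 2 * hp - 1


def select_representative(members: Iterable[Helix]) -> Helix:
    """Representative of a group of similar helices: largest span first,
    then highest degree of saturation (most stacked pairs), then 5'-most."""
    members = list(members)
    if not members:
        raise ValueError("cannot select a representative from an empty group")
    return max(members, key=lambda h: (h.span, h.length, -h.i))


@dataclass(frozen=True)
class Bundle:
    """A window-bounded group of similar helices with one representative.

    The window ``[lo, hi]`` is the extent of the bundle's anchor pair; the
    representative is the saturated stack anchored there.  Members are the
    component helices whose full extent lies within the window: each can
    occur only as an alternative to, or nested inside, the representative.
    """

    lo: int
    hi: int
    representative: Helix
    members: Tuple[Helix, ...]

    @property
    def window(self) -> Tuple[int, int]:
        return (self.lo, self.hi)

    @property
    def span(self) -> int:
        return self.hi - self.lo + 1


class BundleList:
    """All bundles of a sequence plus the representative -> members map.

    One bundle per distinct outer-pair extent ``(i, j)`` realised by a
    component with span at most the extent window.  Because windows
    overlap, a small helix typically belongs to several bundles.
    """

    def __init__(
        self,
        ca: ComponentArray,
        params: FoldParams,
        window: Optional[int] = None,
    ):
        if ca.seq is None or ca.pt is None:
            raise ValueError("ComponentArray must carry its sequence and pair table")
        self.params = params
        self.seq = ca.seq
        self.pt = ca.pt
        self.window = (
            window if window is not None else bundle_extent_window(params.L, params.hp)
        )
        self.bundles: List[Bundle] = []
        self._by_extent: Dict[Tuple[int, int], Bundle] = {}
        self._fill_cache: Dict[Tuple[int, int, bool], List[FrozenSet]] = {}

        small = [h for h in ca if h.span <= self.window]
        for (i, j) in sorted({(h.i, h.j) for h in small}):
            rep = self._saturated_stack(i, j)
            members = tuple(sorted(h for h in small if i <= h.i and h.j <= j))
            if rep not in members:
                members = tuple(sorted(members + (rep,)))
            b = Bundle(i, j, rep, members)
            self.bundles.append(b)
            self._by_extent[(i, j)] = b

    def _saturated_stack(self, i: int, j: int) -> Helix:
        """The longest admissible stack anchored at outer pair ``(i, j)``."""
        blocked = self.params.forced_unpaired
        hp = self.params.hp
        length = 0
        while True:
            ii, jj = i + length, j - length
            if ii in blocked or jj in blocked:
                break
            if jj - ii - 1 < hp or not self.pt.pairable(ii, jj):
                break
            length += 1
        if length < self.params.L:
            raise StructureError(f"no admissible stack anchored at ({i}, {j})")
        return Helix(i, j, length)

    def __len__(self) -> int:
        return len(self.bundles)

    def __iter__(self):
        return iter(self.bundles)

    def bundle_at(self, i: int, j: int) -> Optional[Bundle]:
        return self._by_extent.get((i, j))

    @property
    def reference_list(self) -> Dict[Helix, Tuple[Helix, ...]]:
        return {b.representative: b.members for b in self.bundles}

    def dump_tsv(self) -> str:
        """Reference-list export, 1-based coordinates."""
        lines = [
            "rep_start\trep_end\trep_length\tmember_start\tmember_end\tmember_length"
        ]
        for b in self.bundles:
            r = b.representative
            for m in b.members:
                lines.append(
                    f"{r.i + 1}\t{r.j + 1}\t{r.length}\t"
                    f"{m.i + 1}\t{m.j + 1}\t{m.length}"
                )
        return "\n".join(lines) + "\n"

    # -- expansion ---------------------------------------------------------

    def fillings(self, i: int, j: int, outer_exempt: bool) -> List[FrozenSet]:
        """All valid pair sets on ``[i, j]`` anchored at outer pair ``(i, j)``.

        Every maximal stack must reach the minimum helix length, except
        that the stack through ``(i, j)`` is exempt when the enclosing
        structure continues it from outside the window (``outer_exempt``);
        the merged stack is then long enough by construction.  Windows are
        tiny, so brute force is fine; results are cached.
        """
        key = (i, j, outer_exempt)
        cached = self._fill_cache.get(key)
        if cached is not None:
            return cached
        blocked = self.params.forced_unpaired
        hp = self.params.hp
        pt = self.pt

        def admissible(a: int, b: int) -> bool:
            return (
                a not in blocked
                and b not in blocked
                and b - a - 1 >= hp
                and pt.pairable(a, b)
            )

        def enum(lo: int, hi: int) -> List[FrozenSet]:
            if lo >= hi:
                return [frozenset()]
            out = list(enum(lo + 1, hi))  # lo unpaired
            for q in range(lo + hp + 1, hi + 1):
                if not admissible(lo, q):
                    continue
                for inner in enum(lo + 1, q - 1):
                    for rest in enum(q + 1, hi):
                        out.append(frozenset({(lo, q)}) | inner | rest)
            return out

        if not admissible(i, j):
            raise StructureError(f"window anchor ({i}, {j}) cannot pair")
        results = []
        for interior in enum(i + 1, j - 1):
            pairs = frozenset({(i, j)}) | interior
            if self._stacks_ok(pairs, (i, j), outer_exempt):
                results.append(pairs)
        self._fill_cache[key] = results
        return results

    def _stacks_ok(
        self, pairs: FrozenSet, anchor: Tuple[int, int], outer_exempt: bool
    ) -> bool:
        L = self.params.L
        pair_set = set(pairs)
        for i, j in pair_set:
            if (i - 1, j + 1) in pair_set:
                continue  # not the outer pair of a maximal stack
            run = 1
            while (i + run, j - run) in pair_set:
                run += 1
            if run < L and not (outer_exempt and (i, j) == anchor):
                return False
        return True


def bundle_components(
    ca: ComponentArray, params: FoldParams, window: Optional[int] = None
) -> BundleList:
    """Group all similar helices of a component list into bundles.

    Every component whose extent fits the extent window joins the bundle of
    each anchor that covers it (bundles overlap, so small helices usually
    belong to several); components wider than the window pass through
    unbundled.
    """
    return BundleList(ca, params, window=window)


def unbundle(
    structures: Iterable[SecondaryStructure], bl: BundleList
) -> Set[SecondaryStructure]:
    """Expand bundled structures back into the full unbundled ensemble.

    Each maximal stack of a bundled structure is decomposed exactly as the
    enumerator built it: outer length-``L`` pieces are stripped until the
    remaining extent fits the extent window (that suffix is a sealed
    representative, substituted by every anchored alternative) or until the
    remainder is a single unbundled component (kept literally).  The
    expansions of distinct bundled structures are disjoint, so the union
    over a complete bundled run reproduces the unbundled ensemble exactly.
    """
    L = bl.params.L
    W = bl.window
    out: Set[SecondaryStructure] = set()
    for s in structures:
        pairs = set(s.pairs)
        literal: Set[Tuple[int, int]] = set()
        occurrences: List[Tuple[int, int, bool]] = []
        for i, j in sorted(pairs):
            if (i - 1, j + 1) in pairs:
                continue  # interior of a maximal stack
            run = 1
            while (i + run, j - run) in pairs:
                run += 1
            ii, jj, rem = i, j, run
            while True:
                if jj - ii + 1 <= W:
                    b = bl.bundle_at(ii, jj)
                    if b is None or b.representative.length != rem:
                        raise StructureError(
                            f"stack at ({ii}, {jj}) x{rem} is not a bundle "
                            "representative of this bundle list"
                        )
                    occurrences.append((ii, jj, (ii - 1, jj + 1) in pairs))
                    break
                if rem <= 2 * L - 1:
                    literal.update((ii + t, jj - t) for t in range(rem))
                    break
                literal.update((ii + t, jj - t) for t in range(L))
                ii += L
                jj -= L
                rem -= L
        expansions = [bl.fillings(i, j, ex) for (i, j, ex) in occurrences]
        for combo in itertools.product(*expansions):
            newpairs = frozenset(literal.union(*combo)) if combo else frozenset(literal)
            out.add(SecondaryStructure(newpairs))
    return out
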