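"""The jump tree: complete, duplicate-free assembly of structures.

Structures are assembled by recursing over intervals.  Within an interval
the enumerator either places no helix at all, or chooses the 5'-most placed
helix and recurses into the *inside* interval (bounded by the helix's inner
edges) and the *behind* interval (from the helix's 3' outer edge to the end
of the containing interval).  Every structure therefore decomposes uniquely
and no duplicates arise.

Long stacks are built from components of length ``L .. 2L - 1`` using the
canonical tiling ``a = (q - 1) * L + (L + k)``: a component may be extended
inward by an adjacent stacked component only when its own length is exactly
``L``, so each maximal stack has exactly one construction route.

Under bundling, any helix whose extent fits the bundling window is placed
as its bundle's saturated representative and its interior is sealed (not
recursed into); :func:`helixcomb.bundles.BundleList.fillings` restores the
alternatives.
"""

from __future__ import annotations

import multiprocessing
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from .bundles import BundleList, bundle_components
from .components import ComponentArray, Helix, build_component_list
from .core import (
    FoldParams,
    PairTable,
    RnaSequence,
    SecondaryStructure,
    maximal_stacks,
)

# adjacency context of an interval: does a helix spanning the interval
# exactly continue the enclosing stack, and is that continuation canonical?
_FREE = 0    # root or behind interval: a spanning helix starts a fresh stack
_ALLOW = 1   # inside a length-L piece: canonical continuation permitted
_BLOCK = 2   # inside a longer piece: continuation would duplicate a tiling


@dataclass(frozen=True)
class StructureFilter:
    """Keep structures with >= ``min_helix_count`` maximal helices of
    length >= ``min_helix_len``."""

    min_helix_count: int = 0
    min_helix_len: int = 1

    def passes(self, s: SecondaryStructure) -> bool:
        if self.min_helix_count == 0:
            return True
        n_ok = sum(1 for ln in maximal_stacks(s) if ln >= self.min_helix_len)
        return n_ok >= self.min_helix_count


def passes_filters(s: SecondaryStructure, f: StructureFilter) -> bool:
    return f.passes(s)


@dataclass
class EnumerationResult:
    """Counts from one enumeration run.  All counts are exact integers.

    ``structure_count`` includes the open (fully unpaired) chain whenever it
    passes the active structure filter; ``folded_count`` excludes it, which
    is the convention used when reporting how many *folds* a sequence has.
    """

    structure_count: int = 0
    filtered_count: int = 0
    component_count: int = 0
    bundle_count: Optional[int] = None
    open_chain_counted: bool = True
    motif_occurrences: Dict[str, int] = field(default_factory=dict)

    @property
    def folded_count(self) -> int:
        return self.structure_count - (1 if self.open_chain_counted else 0)


class _Unit:
    """A placeable unit: a component helix, or a sealed bundle representative."""

    __slots__ = ("helix", "sealed")

    def __init__(self, helix: Helix, sealed: bool):
        self.helix = helix
        self.sealed = sealed


def _build_units(
    ca: ComponentArray, params: FoldParams, bl: Optional[BundleList]
) -> List[List[_Unit]]:
    """Per start position, the placeable units in deterministic order."""
    units: List[List[_Unit]] = [[] for _ in range(ca.n)]
    if bl is None:
        for i in range(ca.n):
            units[i] = [_Unit(h, False) for h in ca.at(i)]
        return units
    window = bl.window
    for i in range(ca.n):
        cell: List[_Unit] = []
        seen_extents: Set[int] = set()
        for h in ca.at(i):
            if h.span > window:
                cell.append(_Unit(h, False))
            elif h.j not in seen_extents:
                seen_extents.add(h.j)
                b = bl.bundle_at(h.i, h.j)
                cell.append(_Unit(b.representative, True))
        cell.sort(key=lambda u: (u.helix.j, u.helix.length))
        units[i] = cell
    return units


class _Occupancy:
    """Next start position (at or after i) holding at least one unit."""

    def __init__(self, units: List[List[_Unit]]):
        n = len(units)
        nxt = [None] * n
        last = None
        for i in range(n - 1, -1, -1):
            if units[i]:
                last = i
            nxt[i] = last
        self._next = nxt
        self.n = n

    def next_occupied(self, i: int) -> Optional[int]:
        if i < 0:
            i = 0
        if i >= self.n:
            return None
        return self._next[i]


class JumpTree:
    """Streaming enumerator over a fixed sequence and parameter set.

    ``restore_behind=False`` is a debug switch that reproduces the naive
    behaviour of examining each behind interval only once before discarding
    it; it loses structures and exists only so tests can demonstrate why the
    behind intervals must be conditionally retained.
    """

    def __init__(
        self,
        seq: RnaSequence,
        params: FoldParams,
        visitor: Optional[Callable] = None,
        structure_filter: Optional[StructureFilter] = None,
        restore_behind: bool = True,
        max_structures: Optional[int] = None,
        use_lookup: bool = True,
    ):
        self.seq = seq
        self.params = params
        self.visitor = visitor
        self.filter = structure_filter or StructureFilter(
            params.min_helix_count, params.min_helix_len_filter
        )
        self.restore_behind = restore_behind
        self.max_structures = max_structures

        self.pt = PairTable(seq)
        self.ca = build_component_list(seq, self.pt, params)
        self.bl = bundle_components(self.ca, params) if params.bundling else None
        self.units = _build_units(self.ca, params, self.bl)
        self._occ = _Occupancy(self.units) if use_lookup else None
        self._min_span = 2 * params.L + params.hp
        self._placed: List[_Unit] = []
        self._result = EnumerationResult(
            component_count=len(self.ca),
            bundle_count=len(self.bl) if self.bl is not None else None,
            open_chain_counted=self.filter.passes(SecondaryStructure(frozenset())),
        )

    # -- public ----------------------------------------------------------

    def run(self, roots: Optional[Sequence[Tuple[int, int]]] = None) -> EnumerationResult:
        """Enumerate all structures; with *roots*, only the subtrees whose
        5'-most unit is one of the given ``(start, index-within-start)``
        unit coordinates (the open chain is not emitted)."""
        n = self.seq.n
        if roots is None:
            self._rec([[0, n - 1, _FREE, None]])
        else:
            for (p, k) in roots:
                unit = self.units[p][k]
                self._place(unit, [0, n - 1, _FREE, None], [])
        return self._result

    @property
    def result(self) -> EnumerationResult:
        return self._result

    # -- recursion -------------------------------------------------------

    def _next_start(self, i: int) -> Optional[int]:
        if self._occ is not None:
            return self._occ.next_occupied(i)
        n = len(self.units)
        for p in range(max(i, 0), n):
            if self.units[p]:
                return p
        return None

    def _rec(self, pending: List[list]) -> None:
        if not pending:
            self._emit()
            return
        iv = pending.pop()
        lo, hi, adj, once = iv
        fresh = once is None or not once[0]
        if once is not None:
            once[0] = True
        # branch: no helix starts inside this interval
        self._rec(pending)
        if fresh and hi - lo + 1 >= self._min_span:
            p = self._next_start(lo)
            while p is not None and p + self._min_span - 1 <= hi:
                for unit in self.units[p]:
                    h = unit.helix
                    if h.j > hi:
                        break  # units sorted by 3' end
                    if adj == _BLOCK and h.i == lo and h.j == hi:
                        continue  # non-canonical stack continuation
                    self._place(unit, [lo, hi, adj, once], pending)
                p = self._next_start(p + 1)
        pending.append(iv)

    def _place(self, unit: _Unit, iv: list, pending: List[list]) -> None:
        h = unit.helix
        hi = iv[1]
        self._placed.append(unit)
        n_pushed = 1
        once = None if self.restore_behind else [False]
        pending.append([h.j + 1, hi, _FREE, once])
        if not unit.sealed:
            adj = _ALLOW if h.length == self.params.L else _BLOCK
            pending.append([h.i + h.length, h.j - h.length, adj, None])
            n_pushed = 2
        self._rec(pending)
        for _ in range(n_pushed):
            pending.pop()
        self._placed.pop()

    def _emit(self) -> None:
        res = self._result
        if self.filter.min_helix_count == 0 and self.visitor is None:
            res.structure_count += 1
            return
        pairs = frozenset(
            p for unit in self._placed for p in unit.helix.pairs()
        )
        s = SecondaryStructure(pairs)
        if not self.filter.passes(s):
            res.filtered_count += 1
            return
        res.structure_count += 1
        if self.visitor is not None and (
            self.max_structures is None or res.structure_count <= self.max_structures
        ):
            self.visitor(s)


def enumerate_structures(
    seq: RnaSequence,
    params: FoldParams,
    visitor: Optional[Callable] = None,
    structure_filter: Optional[StructureFilter] = None,
    restore_behind: bool = True,
    max_structures: Optional[int] = None,
    use_lookup: bool = True,
) -> EnumerationResult:
    """Enumerate every structure in the target set and stream it to *visitor*.

    The target set contains every nested pair set over pairable positions
    with hairpin loops of at least ``hp`` nucleotides, every maximal stack
    at least ``L`` pairs long, and no forced-unpaired index paired.  Under
    bundling each representative stands for its whole bundle.  The open
    (fully unpaired) chain is a member of the set.
    """
    tree = JumpTree(
        seq,
        params,
        visitor=visitor,
        structure_filter=structure_filter,
        restore_behind=restore_behind,
        max_structures=max_structures,
        use_lookup=use_lookup,
    )
    return tree.run()


# -- parallel enumeration -------------------------------------------------


def _worker(args) -> Tuple[int, int]:
    residues, params, worker_id, n_workers = args
    seq = RnaSequence("worker", residues)
    tree = JumpTree(seq, params)
    roots = [
        (p, k)
        for p in range(seq.n)
        for k in range(len(tree.units[p]))
    ]
    mine = [r for idx, r in enumerate(roots) if idx % n_workers == worker_id]
    tree.run(roots=mine)
    return tree.result.structure_count, tree.result.filtered_count


def parallel_enumerate(
    seq: RnaSequence, params: FoldParams, n_workers: int = 1
) -> EnumerationResult:
    """Static master/worker split of top-level recursion roots.

    Each top-level root is one unit of the component (or bundle) array used
    as the 5'-most helix of a structure; roots are dealt round-robin to the
    workers and the counts aggregated.  Counts are identical to the serial
    enumeration; only visitation order differs (structures are not streamed).
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if n_workers == 1:
        return enumerate_structures(seq, params)
    tree = JumpTree(seq, params)  # for component/bundle counts and open chain
    open_chain_ok = tree.filter.passes(SecondaryStructure(frozenset()))
    jobs = [(seq.residues, params, w, n_workers) for w in range(n_workers)]
    ctx = multiprocessing.get_context("fork")
    with ctx.Pool(processes=n_workers) as pool:
        parts = pool.map(_worker, jobs)
    result = EnumerationResult(
        component_count=len(tree.ca),
        bundle_count=len(tree.bl) if tree.bl is not None else None,
        open_chain_counted=open_chain_ok,
    )
    result.structure_count = sum(p[0] for p in parts) + (1 if open_chain_ok else 0)
    result.filtered_count = sum(p[1] for p in parts) + (0 if open_chain_ok else 1)
    return result
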