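"""Ensemble analysis: motif search, conformational entropy, modification scans.

Motifs are sequence+structure patterns matched against every structure of an
ensemble as it streams out of the enumerator.  The motif alphabet follows
the usual convention for describing protein- and drug-binding RNA loops:
``A/C/G/U`` literal, ``N`` any nucleotide, ``R`` purine (A or G), ``W`` a
nucleotide engaged in a Watson-Crick pair, and ``_`` a gap of any number of
intervening nucleotides separating the strands of the motif.  The aligned
structure pattern uses ``.`` (unpaired), ``(`` / ``)`` (paired, with the
matching bracket of the pattern identifying the partner) and ``_`` at the
same gap positions.

Conformational entropy differences come from counting microstates:
``dS = R ln(W1 / W0)`` with the molar gas constant R, where W counts the
possible folds of the sequence under each condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .core import (
    FoldParams,
    RnaSequence,
    SecondaryStructure,
    is_watson_crick,
)
from .enumerate import EnumerationResult, enumerate_structures

#: Molar gas constant, J/(mol*K).  Microstate counting gives S = k ln W per
#: molecule; reported per mole, k N_A = R.
GAS_CONSTANT_R = 8.314

SEQ_ALPHABET = frozenset("ACGUWNR")
STRUCT_ALPHABET = frozenset(".()")


class MotifError(ValueError):
    """Malformed motif definition."""


@dataclass(frozen=True)
class Motif:
    """A validated sequence+structure motif.

    ``seq_segments`` and ``struct_segments`` are the per-strand pieces
    obtained by splitting the patterns at ``_``; ``pair_map`` maps each
    ``(``-position to its matching ``)``-position in flattened motif
    coordinates (gaps carry no coordinate).
    """

    name: str
    seq_pattern: str
    struct_pattern: str
    seq_segments: Tuple[str, ...] = field(default=(), compare=False)
    struct_segments: Tuple[str, ...] = field(default=(), compare=False)
    pair_map: Tuple[Tuple[int, int], ...] = field(default=(), compare=False)

    @property
    def segment_lengths(self) -> Tuple[int, ...]:
        return tuple(len(s) for s in self.seq_segments)


def parse_motif(name: str, seq_pattern: str, struct_pattern: str) -> Motif:
    """Validate and compile a motif definition.

    The two patterns must have gaps at the same strand boundaries and equal
    strand lengths; parentheses must balance; every ``W`` must sit at a
    paired position (``W`` asserts membership in a Watson-Crick pair, which
    only a paired nucleotide can satisfy).
    """
    if not seq_pattern or not struct_pattern:
        raise MotifError(f"motif {name!r}: empty pattern")
    seq_pattern = seq_pattern.upper().replace("T", "U")
    seq_segments = tuple(seq_pattern.split("_"))
    struct_segments = tuple(struct_pattern.split("_"))
    if len(seq_segments) != len(struct_segments):
        raise MotifError(
            f"motif {name!r}: sequence and structure patterns have different "
            f"numbers of strands"
        )
    for ss, ts in zip(seq_segments, struct_segments):
        if len(ss) != len(ts):
            raise MotifError(
                f"motif {name!r}: strand length mismatch ({ss!r} vs {ts!r})"
            )
        if not ss:
            raise MotifError(f"motif {name!r}: empty strand")
    flat_seq = "".join(seq_segments)
    flat_struct = "".join(struct_segments)
    for ch in flat_seq:
        if ch not in SEQ_ALPHABET:
            raise MotifError(f"motif {name!r}: illegal sequence symbol {ch!r}")
    for ch in flat_struct:
        if ch not in STRUCT_ALPHABET:
            raise MotifError(f"motif {name!r}: illegal structure symbol {ch!r}")
    stack: List[int] = []
    pair_map: List[Tuple[int, int]] = []
    for pos, ch in enumerate(flat_struct):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise MotifError(f"motif {name!r}: unbalanced ')'")
            pair_map.append((stack.pop(), pos))
    if stack:
        raise MotifError(f"motif {name!r}: unbalanced '('")
    for pos, ch in enumerate(flat_seq):
        if ch == "W" and flat_struct[pos] == ".":
            raise MotifError(
                f"motif {name!r}: W at unpaired position {pos} (W asserts a "
                "Watson-Crick pair)"
            )
    return Motif(
        name=name,
        seq_pattern=seq_pattern,
        struct_pattern=struct_pattern,
        seq_segments=seq_segments,
        struct_segments=struct_segments,
        pair_map=tuple(pair_map),
    )


def _residue_matches(
    sym: str, pos: int, residues: str, partner: Sequence[int], wc_only: bool
) -> bool:
    r = residues[pos]
    if sym == "N":
        return True
    if sym == "R":
        return r in "AG"
    if sym == "W":
        p = partner[pos]
        if p < 0:
            return False
        if wc_only:
            return is_watson_crick(r, residues[p])
        return True
    return r == sym


def count_motif(
    seq: RnaSequence,
    s: SecondaryStructure,
    motif: Motif,
    wc_only: bool = True,
) -> int:
    """Number of distinct placements of *motif* in structure *s*.

    A placement assigns each motif strand a sequence offset (strands in
    order, separated by gaps of length >= 0).  Structure symbols must match
    exactly: ``.`` on an unpaired position, brackets on positions paired
    with each other as dictated by the pattern's own bracket matching.
    ``wc_only`` restricts ``W`` to A-U/G-C pairs (set False to admit G-U).
    """
    n = seq.n
    partner = s.partner_array(n)
    lengths = motif.segment_lengths
    k = len(lengths)
    flat_seq = "".join(motif.seq_segments)
    flat_struct = "".join(motif.struct_segments)
    pair_of = {}
    for a, b in motif.pair_map:
        pair_of[a] = b
        pair_of[b] = a

    # flattened motif coordinate of the first position of each strand
    strand_base = [0] * k
    for t in range(1, k):
        strand_base[t] = strand_base[t - 1] + lengths[t - 1]

    count = 0

    def seq_pos(offsets: List[int], flat: int) -> int:
        # map flattened motif coordinate to a sequence position
        t = k - 1
        while strand_base[t] > flat:
            t -= 1
        return offsets[t] + (flat - strand_base[t])

    def check(offsets: List[int]) -> bool:
        for t in range(k):
            o = offsets[t]
            for u in range(lengths[t]):
                flat = strand_base[t] + u
                pos = o + u
                sc = flat_struct[flat]
                if sc == ".":
                    if partner[pos] != -1:
                        return False
                else:
                    want = seq_pos(offsets, pair_of[flat])
                    if partner[pos] != want:
                        return False
                if not _residue_matches(flat_seq[flat], pos, seq.residues, partner, wc_only):
                    return False
        return True

    def place(t: int, start: int, offsets: List[int]) -> None:
        nonlocal count
        if t == k:
            if check(offsets):
                count += 1
            return
        remaining = sum(lengths[t:])
        for o in range(start, n - remaining + 1):
            offsets.append(o)
            place(t + 1, o + lengths[t], offsets)
            offsets.pop()

    place(0, 0, [])
    return count


def percent_occurrence(occurrences: int, structure_count: int) -> float:
    """Motif occurrences per 100 generated structures, to 2 decimals."""
    if structure_count <= 0:
        raise ValueError("structure count must be positive")
    return round(100.0 * occurrences / structure_count, 2)


@dataclass
class MotifCount:
    motif: Motif
    occurrences: int
    structures_with_hit: int
    structure_count: int

    @property
    def percent(self) -> float:
        return percent_occurrence(self.occurrences, self.structure_count)


def count_motifs_in_ensemble(
    seq: RnaSequence,
    params: FoldParams,
    motifs: Sequence[Motif],
    wc_only: bool = True,
) -> Tuple[EnumerationResult, List[MotifCount]]:
    """Stream the full ensemble once, counting every motif per structure.

    Structures are scanned as they are generated and immediately discarded;
    under bundling the scan runs on the representative structures actually
    visited.  Occurrences (not structures-with-occurrence) are the primary
    count; the number of structures containing at least one hit is also
    reported.
    """
    occ = [0] * len(motifs)
    with_hit = [0] * len(motifs)

    def visitor(s: SecondaryStructure) -> None:
        for idx, m in enumerate(motifs):
            c = count_motif(seq, s, m, wc_only=wc_only)
            occ[idx] += c
            if c:
                with_hit[idx] += 1

    result = enumerate_structures(seq, params, visitor=visitor)
    result.motif_occurrences = {m.name: occ[i] for i, m in enumerate(motifs)}
    counts = [
        MotifCount(m, occ[i], with_hit[i], result.structure_count)
        for i, m in enumerate(motifs)
    ]
    return result, counts


# -- conformational entropy -------------------------------------------------


def entropy_delta(w_constrained: int, w_unconstrained: int) -> float:
    """Entropy difference R ln(W1/W0) in J/(mol K) between two fold counts.

    Negative when constraints reduce the number of possible folds.
    Antisymmetric under swapping the arguments and additive over composed
    ratios.
    """
    if w_constrained < 1 or w_unconstrained < 1:
        raise ValueError("fold counts must be >= 1 to take a log ratio")
    return GAS_CONSTANT_R * math.log(w_constrained / w_unconstrained)


@dataclass
class ModificationScan:
    """Counts and entropies from incremental forced-unpaired constraints."""

    positions: Tuple[int, ...]              # 0-based, 5'->3'
    counts: Tuple[int, ...]                 # level v: first v positions enforced
    percent_reduction: Tuple[float, ...]    # vs level 0
    entropy_vs_unconstrained: Tuple[float, ...]  # R ln(W_v / W_0)
    entropy_marginal: Tuple[float, ...]     # R ln(W_v / W_{v-1})

    @property
    def per_modification_entropy(self) -> Optional[float]:
        """Total entropy change divided by the number of enforced
        modifications (None when no positions were scanned)."""
        m = len(self.positions)
        if m == 0:
            return None
        return self.entropy_vs_unconstrained[-1] / m


def modification_scan(
    seq: RnaSequence,
    modified_positions: Sequence[int],
    params: FoldParams,
) -> ModificationScan:
    """Fold counts as modified nucleotides are enforced unpaired one by one.

    Constraints are applied cumulatively in 5'->3' order: level ``v`` forces
    the first ``v`` modified positions (plus any forced-unpaired positions
    already in *params*) to stay single-stranded.  Counts are structure
    counts of the full ensemble and are monotone non-increasing in ``v``.
    """
    positions = tuple(sorted(modified_positions))
    if any(p < 0 or p >= seq.n for p in positions):
        raise ValueError("modified position out of range")
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate modified position")
    base = frozenset(params.forced_unpaired)
    counts: List[int] = []
    for v in range(len(positions) + 1):
        p = params.with_forced_unpaired(base | frozenset(positions[:v]))
        counts.append(enumerate_structures(seq, p).structure_count)
    w0 = counts[0]
    pct = tuple(round(100.0 * (1 - w / w0), 2) for w in counts)
    dS = tuple(entropy_delta(w, w0) for w in counts)
    marginal = tuple(
        0.0 if v == 0 else entropy_delta(counts[v], counts[v - 1])
        for v in range(len(counts))
    )
    return ModificationScan(
        positions=positions,
        counts=tuple(counts),
        percent_reduction=pct,
        entropy_vs_unconstrained=dS,
        entropy_marginal=marginal,
    )
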