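# Methods

## The enumeration problem

An RNA secondary structure is a set of base pairs over a sequence of
A/C/G/U nucleotides in which each nucleotide pairs at most once and pairs
never cross (pseudoknots are excluded). Pairing is Watson-Crick (A-U, C-G)
plus the G-U wobble. helixcomb enumerates, exactly once each, *every*
structure a sequence can form under three structural constraints:

* **hairpin loop** — a pair `(i, j)` requires `j − i − 1 ≥ hp` unpaired-or-
  paired nucleotides between its partners (`hp = 3` by default: an RNA
  backbone needs three nucleotides to fold back on itself);
* **minimum helix length** — every *maximal stack* (maximal run of
  consecutively stacked pairs `(i, j), (i+1, j−1), …`) must contain at
  least `L` pairs. `L = 2` removes lonely pairs — single, isolated,
  unstacked pairs that do not occur in natural RNA structures;
* **forced-unpaired positions** — nucleotides (e.g. carrying chemical
  modifications that block Watson-Crick pairing) that may not appear in
  any pair.

There is no scoring function: the output is the complete conformational
ensemble, intended for downstream counting, motif statistics, and
entropy estimates, not for picking a single predicted fold.

## Components and the canonical stack decomposition

The unit of combination is the *helix component*: a contiguous stack of
`len ∈ [L, 2L−1]` pairs with outer pair `(i, j)`, inner gap ≥ `hp`,
touching no forced-unpaired position. Sub-runs of longer maximal runs are
included, because long stacks are assembled from adjacent components. The
cap at `2L − 1` plus a canonical tiling rule make every structure reachable
by exactly one construction path: a maximal stack of total length `a`
decomposes uniquely as `a = (q − 1)·L + (L + k)`, `0 ≤ k < L` — outer
pieces of length exactly `L`, one innermost piece of length `L + k`. In
the enumerator this is enforced locally: a component may be extended by an
adjacent stacked component only if its own length is exactly `L`.

## The jump tree

Enumeration recurses over intervals. For an interval, either no placed
helix starts inside it, or the 5'-most placed helix `h` is chosen; placing
`h` spawns an *inside* interval (bounded by the inner edges of `h`) and a
*behind* interval (from just after `h`'s 3' end to the end of the
containing interval). Since every structure decomposes uniquely by its
5'-most helix, the recursion is duplicate-free; since behind intervals are
retained and re-explored for every inside configuration (the full cross
product), it is complete. A debug switch (`restore_behind=False`)
reproduces the naive strategy of examining each behind interval once and
discarding it; tests show it loses structures, which is why the retention
("restore interval") mechanism exists. An interval lookup table lets scans
skip start positions with no components; it changes cost only, never
output (A/B-tested).

Counts are Python integers (arbitrary precision, exact). Structures are
streamed to a visitor and discarded — nothing is accumulated unless the
caller accumulates.

The open (fully unpaired) chain is a member of the ensemble and is
included in `structure_count`; `folded_count` excludes it. Published
benchmark tables for this enumeration problem follow the folded
convention, while the classic "the 14mer folds into 119 structures" figure
includes the open chain; the result object carries both so either
convention is one attribute away.

## Bundling

Helices anchored at a common outer pair within a short window are mutually
exclusive alternatives or nested elaborations of one another. A *bundle*
abstracts all alternatives anchored at one outer-pair extent `(i, j)`
behind a single *representative*: the maximally saturated stack at that
anchor (largest span, then most stacked pairs). During a bundled run the
enumerator places the representative whenever it would place any component
of span at most the extent window, and seals the window interior (no
recursion inside). This collapses all interior alternatives of every
window into one counted structure.

Two window formulas appear in the API. `bundling_window = 4L + 2hp − 1`
is the classical similarity bound — one nucleotide short of the minimum
span holding two side-by-side minimal helices. The threshold actually used
to decide which anchors are sealed is `bundle_extent_window = 6L + 2hp − 1`
(one short of a minimal helix next to a two-component stack). The wider
value is the one consistent with anchored-alternative bundling: it was
fixed by calibrating the bundle and bundled-structure counts of the
package against the reference benchmark set (the designed 14mer and its
2x/3x concatamers and a 76-nt tRNA across minimum helix lengths 2–6), all
of which it reproduces exactly, whereas the narrower bound reproduces
none.

`unbundle` inverts the abstraction. Each maximal stack of a bundled
structure is walked from the outside exactly as the enumerator built it:
length-`L` pieces are stripped while the remaining extent exceeds the
window; the remaining suffix is either a literal innermost component or a
sealed representative. Every sealed occurrence is substituted by every
valid *anchored filling* of its window — each nested pair set on `[i, j]`
containing the pair `(i, j)`, hairpin-valid, with all maximal stacks ≥ `L`
except that the anchored stack may be shorter when the enclosing structure
continues it from outside the window (the merged stack is then long enough
by construction). Expansions of distinct bundled structures are disjoint,
so the union over a complete bundled run is exactly the unbundled
ensemble; this set equality is asserted over hundreds of randomized
instances and on the concatamer fixtures.

Bundling is worthwhile for sequences long enough that the recursion
dominates; for very short inputs the bundling step costs more than it
saves, so the CLI enables it automatically at n ≥ 28 (overridable with
`--bundle/--no-bundle`; the library takes an explicit flag).

## Brute-force oracle

`oracle_enumerate` is the correctness reference: the classic sweep in
which position `i` is either unpaired or paired with each admissible `j`,
followed by post-hoc filtering on the maximal-stack criterion. It shares
no machinery with the jump tree (no components, no intervals, no tiling),
so coincident bugs are unlikely. Cost is exponential; it refuses `n > 25`
by default. The equivalence suite compares the two enumerators as *sets of
pair sets* (not counts) over randomized sequences, lengths 8–20, `L ∈
{1,2,3}`, `hp ∈ {3,4}`, with random forced-unpaired sets.

## Parallel enumeration

`parallel_enumerate` implements a coarse static split: every component (or
bundle representative) is a top-level recursion root — the 5'-most helix
of the structures it seeds — and roots are dealt round-robin to a
`multiprocessing` pool. Aggregated counts are identical to the serial run
(asserted for 1–5 workers); visitation order is not defined, so the
parallel path is count-only. Dynamic load balancing (work stealing) is out
of scope; imbalance is accepted.

## Motif search

A motif pairs a sequence pattern over `{A,C,G,U,N,R,W}` with an aligned
dot-parentheses pattern; `_` in both marks a gap of any length ≥ 0
separating the motif's strands. Matching is positional: `.` requires an
unpaired nucleotide; `(`/`)` require the nucleotide to be paired exactly
with the position aligned to the pattern's matching bracket; `N` is any
nucleotide, `R` a purine, and `W` a nucleotide whose pair is Watson-Crick
(A-U or G-C — wobble G-U is rejected by default, a toggle admits it).
Occurrences are counted per structure as the ensemble streams by, and the
primary statistic is occurrences divided by total structures generated
(×100), which can exceed 100% when a structure contains several hits;
structures-with-at-least-one-hit is reported alongside. Matching is
verified against an independent all-offsets matcher in the tests.

## Conformational entropy and modification scans

Counting microstates gives `S = k ln W` per molecule; reported per mole
with `R = N_A k = 8.314 J/(mol·K)`, an entropy *difference* between two
conditions is `ΔS = R ln(W₁/W₀)` — negative when constraints shrink the
ensemble, antisymmetric, and additive over composed ratios (tested).

`modification_scan` emulates the analysis of naturally modified
nucleotides: constraints are enforced cumulatively 5'→3' (first the
5'-most modified position, then the next, …), and the full ensemble is
recounted at every level. It reports the count curve, percent reduction
versus the unconstrained ensemble, cumulative and marginal entropy
differences, and the per-modified-nucleotide mean. Counts use
`structure_count` (open chain included) so the log-ratio is defined even
for fully constrained sequences; for realistic ensembles the two counting
conventions differ by one structure in millions and the effect on ΔS is
negligible. Counts are monotone non-increasing in the number of enforced
constraints (tested per level against the oracle).

## Problem sizes and numerical choices

The test and acceptance workloads are chosen to be exhaustive where
exhaustiveness is cheap: the 14mer/28mer/42mer reference family (up to
67,014 folded structures), 200+ randomized oracle-equivalence instances at
n ≤ 20, and window fillings (≤ 17 nt at L=2) enumerated by brute force
with caching. Larger published workloads (76-nt tRNAs at ~10⁹ structures,
a 141-nt retroviral RNA at ~10¹⁰ bundled structures) use the same code
paths — counting is exact integer arithmetic throughout — but need
cluster-scale time; the CLI streams structures and never stores the
ensemble, so memory is not the limit.

Determinism: components are ordered by (start, 3' end, length); bundles by
anchor extent; enumeration order is a pure function of these, so re-runs
are bit-identical, and the random fixture generator is seeded. Ties in
representative selection (equal span and saturation cannot actually tie at
one anchor) would fall back to the 5'-most start.

## Known limitations

* No thermodynamics: no free energies, probabilities, or centroid
  structures; the ensemble is unweighted.
* No pseudoknots, no noncanonical pairs beyond G-U (the pairing predicate
  is the single extension point).
* The synthetic fixtures (uniform random A/C/G/U and tandem concatamers)
  exercise combinatorial completeness, not biological realism: real
  sequences have skewed composition and long-range structure, which affect
  ensemble sizes but not the correctness properties tested.
* The parallel backend shares nothing and splits statically; speedup on
  heavily imbalanced recursions is limited.
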