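import itertools
import math
import random

import pytest

from helixcomb import (
    FoldParams,
    GAS_CONSTANT_R,
    RnaSequence,
    count_motif,
    count_motifs_in_ensemble,
    entropy_delta,
    enumerate_structures,
    is_watson_crick,
    modification_scan,
    parse_dot_bracket,
    parse_motif,
    percent_occurrence,
)
from helixcomb.analysis import MotifError
from helixcomb.oracle import oracle_enumerate

GNRA = ("GNRA", "WWWGNRAWWW", "(((....)))")
HIV_TAR = ("HIV TAR", "WWAUCUGWW_WWCUWW", "(((...(((_))))))")


# -- motif grammar ----------------------------------------------------------


def test_parse_valid_motifs():
    m = parse_motif(*GNRA)
    assert m.segment_lengths == (10,)
    assert len(m.pair_map) == 3
    tar = parse_motif(*HIV_TAR)
    assert tar.segment_lengths == (9, 6)
    assert len(tar.pair_map) == 6


@pytest.mark.parametrize(
    "name,seqp,structp",
    [
        ("w-unpaired", "WN", ".."),
        ("unbalanced", "NNN", "(()"),
        ("len-mismatch", "NN", "..."),
        ("strand-mismatch", "NN_NN", "...."),
        ("bad-symbol", "NZ", ".."),
        ("bad-struct", "NN", ".["),
    ],
)
def test_parse_rejects_malformed_motifs(name, seqp, structp):
    with pytest.raises(MotifError):
        parse_motif(name, seqp, structp)


# -- matching ---------------------------------------------------------------


def naive_count(seq, s, motif, wc_only=True):
    """Independent all-offsets matcher used as the oracle."""
    partner = s.partner_array(seq.n)
    segs_s = motif.seq_segments
    segs_t = motif.struct_segments
    lengths = [len(x) for x in segs_s]
    k = len(lengths)
    total = 0
    for offsets in itertools.product(range(seq.n + 1), repeat=k):
        if any(
            offsets[t] + lengths[t] > (offsets[t + 1] if t + 1 < k else seq.n)
            for t in range(k)
        ):
            continue
        # map flattened motif index -> sequence position
        posmap = []
        for t in range(k):
            posmap.extend(offsets[t] + u for u in range(lengths[t]))
        flat_struct = "".join(segs_t)
        flat_seq = "".join(segs_s)
        stack, pairs = [], {}
        for idx, ch in enumerate(flat_struct):
            if ch == "(":
                stack.append(idx)
            elif ch == ")":
                a = stack.pop()
                pairs[a] = idx
                pairs[idx] = a
        good = True
        for idx, ch in enumerate(flat_struct):
            pos = posmap[idx]
            if ch == "." and partner[pos] != -1:
                good = False
            elif ch in "()" and partner[pos] != posmap[pairs[idx]]:
                good = False
        for idx, ch in enumerate(flat_seq):
            pos = posmap[idx]
            r = seq.residues[pos]
            if ch in "ACGU" and r != ch:
                good = False
            elif ch == "R" and r not in "AG":
                good = False
            elif ch == "W":
                p = partner[pos]
                if p == -1:
                    good = False
                elif wc_only and not is_watson_crick(r, seq.residues[p]):
                    good = False
        if good:
            total += 1
    return total


def test_gnra_tetraloop_single_hit():
    seq = RnaSequence("g", "GCGGAAACGC")
    s = parse_dot_bracket("(((....)))")
    assert count_motif(seq, s, parse_motif(*GNRA)) == 1


def test_paired_motif_never_matches_open_chain():
    seq = RnaSequence("g", "GCGGAAACGC")
    s = parse_dot_bracket("..........")
    for m in (GNRA, HIV_TAR):
        assert count_motif(seq, s, parse_motif(*m)) == 0


def test_wobble_closing_pair_fails_w_but_passes_with_toggle():
    # closing pair G-U is wobble: W rejects it unless the toggle admits G-U
    seq = RnaSequence("g", "GCUGAAAAGU")
    s = parse_dot_bracket("((......))")
    m = parse_motif("mini", "WN_NW", "((_))")
    assert count_motif(seq, s, m, wc_only=True) == 0
    assert count_motif(seq, s, m, wc_only=False) > 0


def test_motif_matcher_equals_naive_oracle_on_random_ensembles():
    motifs = [
        parse_motif("mini", "WN_NW", "((_))"),
        parse_motif("loop", "WNNW", "(..)"),
        parse_motif("gnra", *GNRA[1:]),
    ]
    rng = random.Random(99)
    checked = 0
    for _ in range(12):
        n = rng.randint(8, 14)
        seq = RnaSequence("r", "".join(rng.choice("ACGU") for _ in range(n)))
        for s in oracle_enumerate(seq, L=1, hp=3):
            for m in motifs:
                assert count_motif(seq, s, m) == naive_count(seq, s, m)
                checked += 1
    assert checked > 100


def test_ensemble_motif_counting_streams_every_structure(mer14):
    m = parse_motif("pair", "WW_WW", "((_))")
    result, counts = count_motifs_in_ensemble(mer14, FoldParams(L=1, hp=3), [m])
    assert result.structure_count == 119
    # independent tally over the oracle ensemble
    want = sum(
        naive_count(mer14, s, m) for s in oracle_enumerate(mer14, L=1, hp=3)
    )
    assert counts[0].occurrences == want
    assert result.motif_occurrences == {"pair": want}
    assert counts[0].structures_with_hit <= 119


def test_gnra_absent_from_incompatible_ensemble(mer14):
    # the 14mer has no GNRA-compatible tetraloop anywhere in its ensemble
    m = parse_motif(*GNRA)
    _, counts = count_motifs_in_ensemble(mer14, FoldParams(L=1, hp=3), [m])
    assert counts[0].occurrences == 0
    assert counts[0].percent == 0.00


# -- percent occurrence and entropy ----------------------------------------


@pytest.mark.parametrize("occ,total,expected", [(0, 1000, 0.0), (25, 1000, 2.5), (1, 3, 33.33)])
def test_percent_occurrence(occ, total, expected):
    assert percent_occurrence(occ, total) == expected


def test_percent_occurrence_rejects_empty_ensemble():
    with pytest.raises(ValueError):
        percent_occurrence(1, 0)


def test_entropy_delta_identities():
    assert entropy_delta(1000, 1000) == 0.0
    assert entropy_delta(1, 3) == pytest.approx(-GAS_CONSTANT_R * math.log(3))
    # antisymmetry and additivity over composed ratios
    assert entropy_delta(7, 20) == pytest.approx(-entropy_delta(20, 7))
    assert entropy_delta(7, 20) + entropy_delta(20, 50) == pytest.approx(
        entropy_delta(7, 50)
    )
    with pytest.raises(ValueError):
        entropy_delta(0, 10)


def test_entropy_of_forcing_the_adenines_unpaired(mer14):
    # every A in the 14mer forced single-stranded vs unconstrained, L=2
    adenines = [i for i, r in enumerate(mer14.residues) if r == "A"][:4]
    w0 = enumerate_structures(mer14, FoldParams(L=2, hp=3)).structure_count
    wc = enumerate_structures(
        mer14, FoldParams(L=2, hp=3, forced_unpaired=frozenset(adenines))
    ).structure_count
    ds = entropy_delta(wc, w0)
    assert ds == pytest.approx(GAS_CONSTANT_R * math.log(wc / w0))
    assert ds < 0


# -- modification scan -------------------------------------------------------


def test_modification_scan_matches_independent_per_level_runs(mer14):
    positions = [i for i, r in enumerate(mer14.residues) if r == "A"]
    params = FoldParams(L=2, hp=3)
    scan = modification_scan(mer14, positions, params)
    assert len(scan.counts) == len(positions) + 1
    # level 0 is the plain enumeration count
    assert scan.counts[0] == enumerate_structures(mer14, params).structure_count
    for v in range(len(positions) + 1):
        want = len(
            oracle_enumerate(mer14, L=2, hp=3, forced_unpaired=set(positions[:v]))
        )
        assert scan.counts[v] == want
    assert list(scan.counts) == sorted(scan.counts, reverse=True)
    assert scan.percent_reduction[0] == 0.0
    assert all(p >= 0 for p in scan.percent_reduction)
    assert scan.per_modification_entropy == pytest.approx(
        scan.entropy_vs_unconstrained[-1] / len(positions)
    )
    assert sum(scan.entropy_marginal) == pytest.approx(
        scan.entropy_vs_unconstrained[-1]
    )


def test_modification_scan_validates_positions(mer14):
    with pytest.raises(ValueError):
        modification_scan(mer14, [99], FoldParams(L=2))
    with pytest.raises(ValueError):
        modification_scan(mer14, [5, 5], FoldParams(L=2))
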