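import pytest

from helixcomb import (
    FoldParams,
    RnaSequence,
    SecondaryStructure,
    StructureFilter,
    enumerate_structures,
    maximal_stacks,
    parallel_enumerate,
    parse_dot_bracket,
    passes_filters,
)
from helixcomb.oracle import oracle_enumerate
from tests.conftest import random_instances

# a sequence where a helix admits both interior and behind content, so the
# enumeration must revisit the behind interval for every interior variant
RESTORE_SCENARIO = "GAGAAACAACGAAAC"


def test_printed_14mer_has_119_structures(mer14):
    result = enumerate_structures(mer14, FoldParams(L=1, hp=3))
    assert result.structure_count == 119


def test_unpairable_sequence_has_only_the_open_chain():
    seq = RnaSequence("a", "AAAA")
    result = enumerate_structures(seq, FoldParams(L=1))
    assert result.structure_count == 1
    assert result.folded_count == 0


def test_folded_count_excludes_open_chain(mer14):
    result = enumerate_structures(mer14, FoldParams(L=2, hp=3))
    assert result.structure_count == 16
    assert result.folded_count == 15


def test_jump_tree_equals_oracle_with_no_duplicates():
    for seq, params in random_instances(60, seed=11, n_range=(8, 18)):
        visited = []
        enumerate_structures(seq, params, visitor=visited.append)
        assert len(visited) == len(set(visited)), "duplicate structures"
        want = oracle_enumerate(
            seq, L=params.L, hp=params.hp, forced_unpaired=params.forced_unpaired
        )
        assert set(visited) == want


def test_lookup_skipping_does_not_change_output():
    for seq, params in random_instances(15, seed=23, n_range=(8, 16)):
        a, b = [], []
        enumerate_structures(seq, params, visitor=a.append, use_lookup=True)
        enumerate_structures(seq, params, visitor=b.append, use_lookup=False)
        assert set(a) == set(b)
        assert len(a) == len(b)


def test_no_lonely_pairs_at_min_helix_two():
    for seq, params in random_instances(25, seed=31, ls=(2,), max_forced=0):
        seen = []
        enumerate_structures(seq, params, visitor=seen.append)
        for s in seen:
            assert all(length >= 2 for length in maximal_stacks(s))


def test_count_monotone_in_min_helix_length():
    seq = RnaSequence("28mer", "GCUCUAAAAGAGAG" * 2)
    counts = [
        enumerate_structures(seq, FoldParams(L=L, hp=3)).structure_count
        for L in (1, 2, 3, 4)
    ]
    assert counts == sorted(counts, reverse=True)


def test_count_monotone_under_forced_unpaired(mer14):
    prev = None
    for k in range(5):
        params = FoldParams(L=1, hp=3, forced_unpaired=frozenset(range(5, 5 + k)))
        c = enumerate_structures(mer14, params).structure_count
        if prev is not None:
            assert c <= prev
        prev = c


def test_restore_interval_regression():
    """Dropping behind intervals after a single examination loses structures."""
    seq = RnaSequence("fig3", RESTORE_SCENARIO)
    params = FoldParams(L=1, hp=3)
    full = enumerate_structures(seq, params)
    crippled = enumerate_structures(seq, params, restore_behind=False)
    assert crippled.structure_count < full.structure_count
    assert full.structure_count == len(oracle_enumerate(seq, L=1, hp=3))


def test_restore_interval_regression_is_widespread():
    lost_somewhere = False
    for seq, params in random_instances(20, seed=77, ls=(1,), max_forced=0):
        full = enumerate_structures(seq, params).structure_count
        crippled = enumerate_structures(seq, params, restore_behind=False).structure_count
        assert crippled <= full
        lost_somewhere |= crippled < full
    assert lost_somewhere


def test_structure_filters():
    f1 = StructureFilter(min_helix_count=1, min_helix_len=1)
    assert not passes_filters(SecondaryStructure(frozenset()), f1)
    s = parse_dot_bracket("(((....)))")
    assert passes_filters(s, StructureFilter(1, 3))
    assert not passes_filters(s, StructureFilter(2, 1))
    two = parse_dot_bracket("((...))((...))")
    assert passes_filters(two, StructureFilter(2, 2))
    assert not passes_filters(two, StructureFilter(2, 3))


def test_filtered_enumeration_counts(mer14):
    params = FoldParams(L=2, hp=3, min_helix_count=1, min_helix_len_filter=3)
    result = enumerate_structures(mer14, params)
    # independently: oracle structures with >= 1 maximal stack of length >= 3
    want = sum(
        1
        for s in oracle_enumerate(mer14, L=2, hp=3)
        if any(length >= 3 for length in maximal_stacks(s))
    )
    assert result.structure_count == want
    assert result.structure_count + result.filtered_count == 16


def test_max_structures_caps_writing_not_counting(mer14):
    seen = []
    result = enumerate_structures(
        mer14, FoldParams(L=1, hp=3), visitor=seen.append, max_structures=10
    )
    assert result.structure_count == 119
    assert len(seen) == 10


@pytest.mark.parametrize("workers", [1, 2, 3])
def test_parallel_parity_on_random_instances(workers):
    for seq, params in random_instances(6, seed=workers, n_range=(12, 18)):
        serial = enumerate_structures(seq, params)
        para = parallel_enumerate(seq, params, n_workers=workers)
        assert para.structure_count == serial.structure_count
        assert para.filtered_count == serial.filtered_count


def test_parallel_parity_with_structure_filter():
    seq = RnaSequence("28mer", "GCUCUAAAAGAGAG" * 2)
    params = FoldParams(L=2, hp=3, min_helix_count=2, min_helix_len_filter=2)
    serial = enumerate_structures(seq, params)
    for workers in (2, 3):
        para = parallel_enumerate(seq, params, n_workers=workers)
        assert para.structure_count == serial.structure_count
        assert para.filtered_count == serial.filtered_count
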