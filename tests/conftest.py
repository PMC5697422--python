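import random

import pytest

from helixcomb import FoldParams, RnaSequence, make_fixture


@pytest.fixture
def mer14() -> RnaSequence:
    """The designed 14-nt oligonucleotide used as the reference benchmark."""
    return make_fixture("printed14mer")


@pytest.fixture
def mer42() -> RnaSequence:
    return make_fixture("concatamer", k=3)


def random_instances(n_trials, seed, n_range=(8, 20), ls=(1, 2, 3), hps=(3, 4),
                     max_forced=3):
    """Deterministic stream of (sequence, params) test instances."""
    rng = random.Random(seed)
    for _ in range(n_trials):
        n = rng.randint(*n_range)
        residues = "".join(rng.choice("ACGU") for _ in range(n))
        L = rng.choice(ls)
        hp = rng.choice(hps)
        forced = frozenset(rng.sample(range(n), rng.randint(0, max_forced)))
        yield RnaSequence(f"rand{n}", residues), FoldParams(
            L=L, hp=hp, forced_unpaired=forced
        )
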