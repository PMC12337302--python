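import itertools

import pytest

from oligopop.dna import revcomp
from oligopop.fidelity import OverhangSet
from oligopop.hingesets import default_hingeset
from oligopop.synth import default_ligation_matrix, synthetic_ligation_matrix


@pytest.fixture(scope="session")
def matrix():
    """The package's default synthetic scoring matrix."""
    return default_ligation_matrix()


@pytest.fixture(scope="session")
def wc_matrix():
    """Watson-Crick-only matrix: every valid set has fidelity 1."""
    return synthetic_ligation_matrix(correct_count=100, mismatch_rate=0.0, seed=1)


@pytest.fixture(scope="session")
def hingeset20():
    return default_hingeset(20)


#: 16-overhang toy alphabet (8 rc-pairs, AATG/GCTT and their partners included)
TOY_ALPHABET = (
    "AATG", "CATT", "GCTT", "AAGC",
    "ACTG", "CAGT", "TTAC", "GTAA",
    "CCAG", "CTGG", "TGGA", "TCCA",
    "GACT", "AGTC", "CTTC", "GAAG",
)


@pytest.fixture(scope="session")
def toy_alphabet():
    assert all(revcomp(a) in TOY_ALPHABET for a in TOY_ALPHABET)
    return TOY_ALPHABET


def toy_valid_sets(size):
    """All valid sets of ``size`` over the toy alphabet containing AATG+GCTT."""
    pairs = []
    seen = set()
    for a in TOY_ALPHABET:
        key = frozenset((a, revcomp(a)))
        if key not in seen and a not in ("AATG", "CATT", "GCTT", "AAGC"):
            seen.add(key)
            pairs.append(tuple(sorted(key)))
    out = []
    for combo in itertools.combinations(pairs, size - 2):
        for picks in itertools.product(*[p for p in combo]):
            out.append(OverhangSet(["AATG", "GCTT", *picks]))
    return out
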