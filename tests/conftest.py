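import numpy as np
import pytest

from pinmap.fixtures import Feature, FixtureSpec, make_genome
from pinmap.kindex import IndexParams, build_index
from pinmap.seqio import SequenceRecord
from pinmap.urbench import revcomp


@pytest.fixture(scope="session")
def small_genome():
    """20 kb i.i.d. random genome: essentially every k-mer is a pin."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    return SequenceRecord("chr1", seq)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index([small_genome], IndexParams(k=24))


@pytest.fixture(scope="session")
def repeat_fixture():
    """60 kb genome with a 600 bp two-copy repeat, an inverted repeat and
    an N-run, plus the planted-feature truth."""
    spec = FixtureSpec(
        length=60_000,
        seed=7,
        features=(
            Feature("repeat", 600, 2),
            Feature("inverted_repeat", 300),
            Feature("n_run", 200),
        ),
    )
    genome, truth = make_genome(spec)
    return genome, truth


@pytest.fixture(scope="session")
def repeat_index(repeat_fixture):
    genome, _ = repeat_fixture
    return build_index([genome], IndexParams(k=24))


@pytest.fixture(scope="session")
def mb_fixture():
    """1 Mb genome: unique backbone + planted duplications; session-wide
    because the index build is the expensive step."""
    spec = FixtureSpec(
        length=1_000_000,
        seed=11,
        features=(
            Feature("repeat", 2_000, 2),
            Feature("inverted_repeat", 800),
            Feature("n_run", 300),
            Feature("overabundant_word", 40, 40),
        ),
    )
    genome, truth = make_genome(spec)
    index = build_index([genome], IndexParams(k=24))
    return genome, truth, index


def make_pair(seq: str, start: int, frag: int, L: int = 150, name: str = "p"):
    """Error-free FR pair from plus-strand fragment [start, start+frag)."""
    r1 = SequenceRecord(f"{name}/1", seq[start : start + L])
    r2 = SequenceRecord(f"{name}/2", revcomp(seq[start + frag - L : start + frag]))
    return r1, r2
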