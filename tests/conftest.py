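import numpy as np
import pytest

from pokeyrec.core_io import Alignment, SequenceRecord


def make_aln(seqs: dict[str, str]) -> Alignment:
    return Alignment([SequenceRecord(k, v) for k, v in seqs.items()])


def random_acgt(rng: np.random.Generator, n: int, L: int) -> Alignment:
    m = rng.choice(list("ACGT"), size=(n, L))
    return make_aln({f"s{i}": "".join(m[i]) for i in range(n)})


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mosaic_scenario():
    """One default mosaic dataset shared by read-only tests."""
    from pokeyrec.synthetic_data import default_mosaic_scenario

    return default_mosaic_scenario(seed=12345)
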