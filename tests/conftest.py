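import numpy as np
import pytest
from hypothesis import settings

from rnagen.sequence_io import AlignedFamily, PairList
from rnagen.synthetic import SyntheticFamilySpec, sample_family

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_family() -> AlignedFamily:
    return AlignedFamily(
        rows=[
            ("r1", "GCGAAUCGC-"),
            ("r2", "GCGUUUCGCA"),
            ("r3", "GCCAAUGGCA"),
            ("r4", "ACG--UCGUA"),
        ],
        ss_cons="<<<....>>>",
        consensus_mask=[True] * 10,
    )


@pytest.fixture(scope="session")
def hairpin_pairs() -> PairList:
    return PairList([(0, 9), (1, 8), (2, 7)])


@pytest.fixture(scope="session")
def small_sample():
    """A small sampled synthetic family shared by statistics tests."""
    spec = SyntheticFamilySpec.default(n_sequences=500, delta=0.9, rng_seed=7)
    return sample_family(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
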