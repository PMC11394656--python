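import pytest

import pirnascape as pk


@pytest.fixture(scope="session")
def study_genome():
    """Default analysis genome: 5 Mb, 15% repeat, 1% gene."""
    return pk.simulate_genome(5_000_000, 0.15, 0.01, seed=1)


@pytest.fixture(scope="session")
def small_genome():
    return pk.simulate_genome(300_000, 0.15, 0.01, seed=0)


@pytest.fixture(scope="session")
def bsb_small(small_genome):
    """A 20k-read default BSB library on the small genome."""
    cfg = pk.GeneratorConfig(n_reads=20_000)
    return pk.simulate_library(cfg, small_genome, "BSB", seed=1)


@pytest.fixture(scope="session")
def references():
    return pk.load_reference_classes()


def make_read(seq: str, rid: str = "r1", count: int = 1) -> pk.SmallRNARead:
    return pk.SmallRNARead(rid, seq, count)
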