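import pytest

from guideforge.fixtures import FixtureSpec, make_genome
from guideforge.systems import get_system


@pytest.fixture(scope="session")
def cas9():
    return get_system("cas9")


@pytest.fixture(scope="session")
def small_genome():
    """Unique random 10 kb genome (no duplications), seeded."""
    genome, truth = make_genome(FixtureSpec(seed=42, chrom_lengths=[10_000], gc_fraction=0.45))
    return genome


@pytest.fixture(scope="session")
def dup_genome():
    """12 kb genome with an exact copy of [2000, 3500) appended."""
    genome, truth = make_genome(
        FixtureSpec(seed=5, chrom_lengths=[12_000], gc_fraction=0.40, duplication=(2000, 3500, 1))
    )
    return genome, truth
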