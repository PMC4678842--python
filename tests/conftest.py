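import numpy as np
import pytest

from ncapeval.refmodel import Genome, GenomicInterval, interval_from_coords, tile_baits

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def make_genome(length: int, seed: int, name: str = "ref") -> Genome:
    return Genome([(name, random_sequence(length, seed))])


@pytest.fixture(scope="session")
def lambda_genome() -> Genome:
    """Synthetic 48 502-bp phage-scale genome (random stand-in for a real
    phage reference; only the geometry matters for these tests)."""
    return make_genome(48_502, seed=11, name="lambda_syn")


@pytest.fixture(scope="session")
def lambda_target() -> GenomicInterval:
    return interval_from_coords("lambda_syn", 41_053, 42_370)


@pytest.fixture(scope="session")
def lambda_baits_M(lambda_genome, lambda_target):
    return tile_baits(lambda_genome, lambda_target, 460, 20)
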