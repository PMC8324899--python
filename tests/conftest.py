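import numpy as np
import pytest

from spacerlink.sequtils import random_dna
from spacerlink.synthetic import CommunityConfig, TimepointSpec, simulate_timeseries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(**overrides) -> CommunityConfig:
    """A fast, high-coverage community for unit-level end-to-end checks."""
    defaults = dict(
        seed=7,
        host_length=30_000,
        n_host_spacers=10,
        n_viruses=2,
        virus_len_range=(6_000, 9_000),
        protospacers_per_virus=3,
        n_background_genomes=1,
        background_len_range=(12_000, 15_000),
        n_reads=20_000,
        virus_weights=(6.0, 3.0),
        timepoints=[TimepointSpec("t0")],
    )
    defaults.update(overrides)
    return CommunityConfig(**defaults)


@pytest.fixture(scope="session")
def small_community():
    return simulate_timeseries(small_config())


def planted_read(rng, dr: str, spacers: list[str], flank: int = 10) -> str:
    """A read consisting of flank + DR (spacer DR)* + flank."""
    parts = [random_dna(rng, flank), dr]
    for s in spacers:
        parts.append(s)
        parts.append(dr)
    parts.append(random_dna(rng, flank))
    return "".join(parts)
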