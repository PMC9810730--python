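"""Shared fixtures: small seeded simulations reused across test modules."""

import pytest

from targhap.simulate import SimConfig, simulate_diploid


@pytest.fixture(scope="session")
def truth_small():
    """60-kb diploid truth used by cheap unit tests."""
    return simulate_diploid(SimConfig(region_length=60_000, seed=1234))


@pytest.fixture(scope="session")
def truth_medium():
    """200-kb diploid truth with one planted deletion and insertion."""
    return simulate_diploid(
        SimConfig(
            region_length=200_000,
            sv_spec=[("DEL", 2889), ("INS", 787)],
            seed=777,
        )
    )
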