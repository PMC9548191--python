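"""Shared fixtures: one desk-scale simulation reused across the suite."""

import pytest

from nmcomp.simulate import desk_config, simulate


@pytest.fixture(scope="session")
def desk_sim():
    """Default desk-scale run: all evolutionary processes active."""
    return simulate(desk_config(seed=101))


@pytest.fixture(scope="session")
def quiet_sim():
    """Desk-scale run with no stochastic events: five collinear genomes."""
    cfg = desk_config(seed=55, loss_rate=0.0, fragmentation_rate=0.0,
                      recombination_rate=0.0, duplication_rate=0.0,
                      aa_divergence=0.0, n_orfans_per_leaf=0)
    return simulate(cfg)
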