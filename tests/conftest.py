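"""Shared fixtures: synthetic cohorts and derived networks.

Expensive objects (the default cohort and its influence network) are
session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from mirti import (
    SimulationConfig,
    build_design,
    build_mirti,
    simulate,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def default_sim(default_cfg):
    """Full-size synthetic cohort at the study-condition defaults."""
    return simulate(default_cfg)


@pytest.fixture(scope="session")
def default_net(default_sim):
    """miRTI network built on the default cohort."""
    sim = default_sim
    return build_mirti(sim.mirna, sim.mrna, sim.fpi, sim.seq)


@pytest.fixture(scope="session")
def default_design(default_sim, default_net):
    return build_design(default_net, list(default_sim.mrna.index))


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced cohort for tests that only need structure, not power."""
    return SimulationConfig(
        n_genes=120,
        n_mirnas=10,
        n_normal=12,
        n_primary=20,
        n_metastatic=4,
        n_modules=4,
        module_size=10,
        n_driver_mirnas=2,
        decoys_per_mirna=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
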