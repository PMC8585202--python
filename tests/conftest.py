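"""Shared fixtures: toy membranes, environments, and the replicate screens
used by the acceptance tests (session-scoped; they are the expensive part)."""

import numpy as np
import pytest

from dipscreen import (
    AgentSpec,
    EnvironmentParams,
    MembraneGeometry,
    SimulationParams,
    get_agent,
    get_lipid,
    make_toy_membrane,
)
from dipscreen.screening import RunConfig, run_screen


@pytest.fixture
def env():
    return EnvironmentParams()


@pytest.fixture
def toy_agent():
    return AgentSpec("toy", mass=600.0, dipole=(2.0, 1.0, -1.5), logp=0.0)


@pytest.fixture
def single_site_membrane():
    """One dipole at the center of a 40 A box, plane at z = 10."""
    return make_toy_membrane(
        [[20.0, 20.0, 0.0]], dipole=(0.0, 0.0, 8.0), geometry=MembraneGeometry(40, 40, 10)
    )


@pytest.fixture
def square_membrane():
    """Four equal dipoles at the corners of a square centered in the box."""
    pts = [[15.0, 15.0, 0.0], [15.0, 25.0, 0.0], [25.0, 15.0, 0.0], [25.0, 25.0, 0.0]]
    return make_toy_membrane(pts, dipole=(0.0, 0.0, 5.0), geometry=MembraneGeometry(40, 40, 10))


def _screen(lipid: str, agent: str):
    config = RunConfig(
        lipid=get_lipid(lipid),
        agent=get_agent(agent),
        geometry=MembraneGeometry(lx=80.0, ly=80.0, half_thickness=20.0),
        env=EnvironmentParams(),
        sim=SimulationParams(),
        n_replicates=10,
    )
    return run_screen(config, base_seed=1)


@pytest.fixture(scope="session")
def screen_oct_pc():
    return _screen("PC", "OCT")


@pytest.fixture(scope="session")
def screen_oct_pg():
    return _screen("PG", "OCT")


@pytest.fixture(scope="session")
def screen_chx_pc():
    return _screen("PC", "CHX")


@pytest.fixture(scope="session")
def screen_chx_pg():
    return _screen("PG", "CHX")
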