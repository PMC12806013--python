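"""Shared fixtures: the replication runs, computed once per session."""

from __future__ import annotations

import pytest

import angiofv as af
from angiofv.experiments import ExperimentSpec


@pytest.fixture(scope="session")
def baseline_traj() -> af.Trajectory:
    """Benchmark run (n=100, T=2) under the replication boundary closure."""
    return af.run(ExperimentSpec("baseline").build_config())


@pytest.fixture(scope="session")
def mu5_traj() -> af.Trajectory:
    """Benchmark run with the Robin influx coefficient raised to μ=5."""
    return af.run(ExperimentSpec("mu_5").build_config())


@pytest.fixture(scope="session")
def chi_half_traj() -> af.Trajectory:
    """Benchmark run with the chemotactic response halved, χ=0.5."""
    return af.run(ExperimentSpec("chi_half").build_config())


@pytest.fixture(scope="session")
def conservative_baseline_traj() -> af.Trajectory:
    """Benchmark run under the default total-flux (EC-mass-conserving) closure."""
    return af.run(af.load_config())
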