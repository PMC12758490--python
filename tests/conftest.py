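"""Shared fixtures.

The expensive objects — simulated trajectories and trained models — are
session-scoped and shared between the end-to-end tests and the acceptance
suite, so each is built exactly once per run.
"""

import numpy as np
import pytest

from thermoflow import SimulationProtocol, ThermoFlowModel, simulate_langevin
from thermoflow.data import FeatureTrajectory
from thermoflow.protocols import (fit_lj7, fit_three_hole, lj7_run,
                                  three_hole_run)
from thermoflow.training import benchmark_folds

# locations of the three-hole potential minima (found numerically once by
# gradient descent; see test_simulators for the check)
THREE_HOLE_MINIMA = {
    "left": (-1.0480, -0.0420),
    "right": (1.0480, -0.0420),
    "upper": (0.0, 1.5370),
}


@pytest.fixture(scope="session")
def three_hole_traj():
    """Training trajectory: 1e7 steps at kT=1, stride 50 -> 2e5 frames."""
    return three_hole_run(seed=7)


@pytest.fixture(scope="session")
def three_hole_val():
    """Independent validation trajectory (8e5 frames) for density references."""
    return three_hole_run(seed=99, n_steps=4 * 10**7)


@pytest.fixture(scope="session")
def joint_three_hole(three_hole_traj):
    """Headline joint model on the three-hole system."""
    return fit_three_hole(three_hole_traj, seed=0)


@pytest.fixture(scope="session")
def fold_benchmark(three_hole_traj):
    """Five-fold joint-vs-baseline comparison on a 5e4-frame slice."""
    traj = FeatureTrajectory(three_hole_traj.frames[:50000].copy(),
                             frame_interval=three_hole_traj.frame_interval)
    return benchmark_folds(
        traj, tau=2.5, lag=10, folds=5, seed=0,
        model_kwargs=dict(n_init_states=4, beta=0.003, sigma0=0.05),
        fit_kwargs=dict(stage1_cycles=6, stage1_epochs=2, stage2_epochs=2,
                        polish_epochs=8),
        baseline_fit_kwargs=dict(stage1_cycles=6, stage1_epochs=2))


@pytest.fixture(scope="session")
def lj7_data():
    """LJ7 runs at the two training temperatures (5e4 snapshots each)."""
    return lj7_run(0.2, seed=11), lj7_run(0.5, seed=12)


@pytest.fixture(scope="session")
def lj7_results(lj7_data):
    return fit_lj7(list(lj7_data), seed=0)


@pytest.fixture(scope="session")
def multi_temperature_results():
    """Joint model trained on two synthetic three-hole temperatures kT=1, 3."""
    tr1 = simulate_langevin(SimulationProtocol(
        n_steps=2_500_000, stride=50, kT=1.0, seed=21))
    tr3 = simulate_langevin(SimulationProtocol(
        n_steps=2_500_000, stride=50, kT=3.0, seed=22))
    tr3.temperature_tag = 3.0
    model = ThermoFlowModel([tr1, tr3], lag=10, n_init_states=4, tau=2.5,
                            beta=0.003, sigma0=0.05)
    res = model.fit(seed=0, stage1_cycles=6, stage1_epochs=2,
                    stage2_epochs=3, polish_epochs=30)
    return tr1, tr3, res
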