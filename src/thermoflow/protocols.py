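"""Reference study protocols for the two built-in systems.

The production simulation protocols match the published settings (three-hole:
5e7 steps at dt = 0.001, recording every 50 steps -> 1e6 frames; LJ7: 1e7
steps recording every 100 -> 1e5 snapshots per temperature).  The training
runs used by the test-suite and the results-reproduction script are
desk-scale versions of the same conditions: shorter trajectories with
identical dynamics, and training schedules sized so one fit takes minutes on
a single core.  The methods note documents the scaled problem sizes.
"""

from __future__ import annotations

import numpy as np

from .model import SPIBModel, ThermoFlowModel
from .simulators import (SimulationProtocol, coordination_moments,
                         coordination_numbers, simulate_langevin, simulate_lj7)

__all__ = [
    "THREE_HOLE_PRODUCTION", "LJ7_PRODUCTION",
    "three_hole_run", "lj7_run",
    "three_hole_model", "three_hole_baseline", "lj7_model",
    "fit_three_hole", "fit_lj7",
]

# printed production protocols
THREE_HOLE_PRODUCTION = SimulationProtocol(
    n_steps=5 * 10**7, dt=0.001, kT=1.0, gamma=0.5, stride=50, seed=0,
    system="three_hole")
LJ7_PRODUCTION = SimulationProtocol(
    n_steps=10**7, dt=0.005, kT=0.2, gamma=1.0, stride=100, seed=0,
    system="lj7")

# desk-scale training sizes (frames; dynamics identical to production)
THREE_HOLE_TRAIN_STEPS = 10**7          # -> 2e5 frames
THREE_HOLE_VALIDATION_STEPS = 4 * 10**7  # -> 8e5 reference frames
LJ7_TRAIN_STEPS = 5 * 10**6             # -> 5e4 snapshots per temperature


def three_hole_run(seed: int = 0, n_steps: int = THREE_HOLE_TRAIN_STEPS,
                   kT: float = 1.0):
    proto = SimulationProtocol(n_steps=n_steps, dt=0.001, kT=kT, gamma=0.5,
                               stride=50, seed=seed, system="three_hole")
    traj = simulate_langevin(proto)
    traj.temperature_tag = kT
    return traj


def lj7_run(kT: float, seed: int = 0, n_steps: int = LJ7_TRAIN_STEPS):
    proto = SimulationProtocol(n_steps=n_steps, dt=0.005, kT=kT, gamma=1.0,
                               stride=100, seed=seed, system="lj7")
    return simulate_lj7(proto)


def three_hole_model(traj, tau: float = 2.5, lag: int = 10) -> ThermoFlowModel:
    """Configured joint model for three-hole descriptor data.

    lag 10 recorded frames = 0.5 time units; 4 initial k-means states; the
    wider 10-block flow used for the headline density fit.
    """
    return ThermoFlowModel(traj, lag=lag, n_init_states=4, tau=tau,
                           beta=0.003, sigma0=0.05,
                           flow_blocks=10, flow_hidden=(48, 48))


def three_hole_baseline(traj, lag: int = 10) -> SPIBModel:
    return SPIBModel(traj, lag=lag, n_init_states=4, beta=0.003, sigma0=0.05)


def fit_three_hole(traj, seed: int = 0, **overrides):
    """Two-step schedule tuned for the three-hole system (short IB stages so
    the latent stays a smooth image of the landscape, long flow polish)."""
    kw = dict(stage1_cycles=5, stage1_epochs=1, stage2_epochs=1,
              polish_epochs=25)
    kw.update(overrides)
    return three_hole_model(traj).fit(seed=seed, **kw)


def lj7_moment_features(trajs) -> np.ndarray:
    """(mu2, mu3) coordination-moment space for initial k-means labels."""
    cols = []
    for t in trajs:
        mu2, mu3 = coordination_moments(coordination_numbers(t.coords))
        cols.append(np.c_[mu2, mu3])
    return np.concatenate(cols)


def lj7_model(trajs, tau: float = 2.0, lag: int = 3) -> ThermoFlowModel:
    """Configured joint model for LJ7 sorted-coordination-number data.

    Initial labels come from k-means (k = 10) on the coordination-moment
    plane; lag 3 recorded frames = 1.5 LJ time units, shorter than the
    isomerization waiting times at the training temperatures but longer than
    intra-basin vibration.
    """
    return ThermoFlowModel(trajs, lag=lag, n_init_states=10, tau=tau,
                           beta=0.003, sigma0=0.05,
                           init_features=lj7_moment_features(trajs))


def fit_lj7(trajs, seed: int = 0, **overrides):
    kw = dict(stage1_cycles=8, stage1_epochs=2, stage2_epochs=2,
              polish_epochs=25)
    kw.update(overrides)
    return lj7_model(trajs).fit(seed=seed, **kw)
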