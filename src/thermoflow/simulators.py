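"""Built-in Langevin data generators.

Two desk-scale systems:

* a single unit-mass particle on the 2-D three-hole potential — two deep
  basins near (+-1, 0) joined by an upper channel (which holds a shallow
  local minimum) and a lower channel;
* the two-dimensional Lennard-Jones 7-particle cluster (LJ7), whose
  metastable states are distinguished by the second and third central
  moments of the per-particle coordination numbers.

Both use a BAOAB-splitting underdamped Langevin integrator, jit-compiled so
the printed production protocols (5e7 / 1e7 steps) run in seconds-to-minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .data import FeatureTrajectory

__all__ = [
    "SimulationProtocol",
    "three_hole_potential",
    "three_hole_gradient",
    "simulate_langevin",
    "lj7_energy_forces",
    "simulate_lj7",
    "coordination_numbers",
    "coordination_moments",
]


@dataclass(frozen=True)
class SimulationProtocol:
    n_steps: int
    dt: float = 0.001
    kT: float = 1.0
    gamma: float = 0.5
    stride: int = 50
    seed: int = 0
    system: str = "three_hole"

    def __post_init__(self):
        if not (self.n_steps >= self.stride >= 1):
            raise ValueError("need n_steps >= stride >= 1")
        if self.dt <= 0 or self.gamma <= 0 or self.kT < 0:
            raise ValueError("dt, gamma must be > 0 and kT >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.stride

    @property
    def frame_interval(self) -> float:
        return self.dt * self.stride


# ---------------------------------------------------------------------------
# three-hole potential
# ---------------------------------------------------------------------------

def three_hole_potential(x, y):
    """Energy of the three-hole surface (vectorized).

    Two -5 wells at (+-1, 0), a -3 well at (0, 5/3) in the upper channel, a
    +3 bump at (0, 1/3) separating the channels, and quartic confinement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (
        3.0 * np.exp(-x**2 - (y - 1.0 / 3.0) ** 2)
        - 3.0 * np.exp(-x**2 - (y - 5.0 / 3.0) ** 2)
        - 5.0 * np.exp(-((x - 1.0) ** 2) - y**2)
        - 5.0 * np.exp(-((x + 1.0) ** 2) - y**2)
        + 0.2 * x**4
        + 0.2 * (y - 1.0 / 3.0) ** 4
    )


def three_hole_gradient(x, y):
    """Analytic gradient (dV/dx, dV/dy) of the three-hole potential."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g1 = 3.0 * np.exp(-x**2 - (y - 1.0 / 3.0) ** 2)
    g2 = -3.0 * np.exp(-x**2 - (y - 5.0 / 3.0) ** 2)
    g3 = -5.0 * np.exp(-((x - 1.0) ** 2) - y**2)
    g4 = -5.0 * np.exp(-((x + 1.0) ** 2) - y**2)
    dx = (
        -2.0 * x * g1
        - 2.0 * x * g2
        - 2.0 * (x - 1.0) * g3
        - 2.0 * (x + 1.0) * g4
        + 0.8 * x**3
    )
    dy = (
        -2.0 * (y - 1.0 / 3.0) * g1
        - 2.0 * (y - 5.0 / 3.0) * g2
        - 2.0 * y * g3
        - 2.0 * y * g4
        + 0.8 * (y - 1.0 / 3.0) ** 3
    )
    return dx, dy


@njit(cache=True)
def _three_hole_force(x, y):
    g1 = 3.0 * np.exp(-x * x - (y - 1.0 / 3.0) ** 2)
    g2 = -3.0 * np.exp(-x * x - (y - 5.0 / 3.0) ** 2)
    g3 = -5.0 * np.exp(-(x - 1.0) ** 2 - y * y)
    g4 = -5.0 * np.exp(-(x + 1.0) ** 2 - y * y)
    fx = -(
        -2.0 * x * g1 - 2.0 * x * g2
        - 2.0 * (x - 1.0) * g3 - 2.0 * (x + 1.0) * g4
        + 0.8 * x ** 3
    )
    fy = -(
        -2.0 * (y - 1.0 / 3.0) * g1 - 2.0 * (y - 5.0 / 3.0) * g2
        - 2.0 * y * g3 - 2.0 * y * g4
        + 0.8 * (y - 1.0 / 3.0) ** 3
    )
    return fx, fy


@njit(cache=True)
def _run_three_hole(n_steps, dt, kT, gamma, stride, seed, x0, y0):
    np.random.seed(seed)
    n_frames = n_steps // stride
    out = np.empty((n_frames, 2))
    x, y = x0, y0
    vx, vy = 0.0, 0.0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    fx, fy = _three_hole_force(x, y)
    k = 0
    for step in range(n_steps):
        vx += 0.5 * dt * fx
        vy += 0.5 * dt * fy
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        vx = c1 * vx + c2 * np.random.standard_normal()
        vy = c1 * vy + c2 * np.random.standard_normal()
        x += 0.5 * dt * vx
        y += 0.5 * dt * vy
        fx, fy = _three_hole_force(x, y)
        vx += 0.5 * dt * fx
        vy += 0.5 * dt * fy
        if (step + 1) % stride == 0:
            out[k, 0] = x
            out[k, 1] = y
            k += 1
        if not (np.isfinite(x) and np.isfinite(y)) or abs(x) > 1e3 or abs(y) > 1e3:
            return out[:0], step
    return out, -1


def simulate_langevin(protocol: SimulationProtocol, start=(-1.0, 0.0)) -> FeatureTrajectory:
    """Underdamped (BAOAB) Langevin trajectory on the three-hole potential.

    Records (x, y) every `stride` steps; seeded and bit-reproducible.
    """
    frames, failed = _run_three_hole(
        protocol.n_steps, protocol.dt, protocol.kT, protocol.gamma,
        protocol.stride, protocol.seed, float(start[0]), float(start[1]),
    )
    if failed >= 0:
        raise FloatingPointError(
            f"trajectory diverged at step {failed}; reduce dt={protocol.dt}"
        )
    return FeatureTrajectory(frames, frame_interval=protocol.frame_interval,
                             temperature_tag=1.0)


# ---------------------------------------------------------------------------
# Lennard-Jones 7 cluster (2-D)
# ---------------------------------------------------------------------------

def lj7_energy_forces(coords: np.ndarray):
    """Pairwise 12-6 Lennard-Jones energy and forces (epsilon = sigma = 1)."""
    coords = np.asarray(coords, dtype=float).reshape(7, 2)
    energy = 0.0
    forces = np.zeros((7, 2))
    for i in range(7):
        for j in range(i + 1, 7):
            d = coords[i] - coords[j]
            r2 = float(d @ d)
            if r2 == 0.0:
                raise ValueError(f"particles {i} and {j} coincide")
            inv6 = 1.0 / r2**3
            energy += 4.0 * (inv6 * inv6 - inv6)
            fmag = 24.0 * (2.0 * inv6 * inv6 - inv6) / r2
            forces[i] += fmag * d
            forces[j] -= fmag * d
    return energy, forces


@njit(cache=True)
def _lj7_forces_jit(pos, k_restraint, r_restraint):
    forces = np.zeros((7, 2))
    for i in range(7):
        for j in range(i + 1, 7):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            r2 = dx * dx + dy * dy
            inv6 = 1.0 / (r2 * r2 * r2)
            fmag = 24.0 * (2.0 * inv6 * inv6 - inv6) / r2
            forces[i, 0] += fmag * dx
            forces[i, 1] += fmag * dy
            forces[j, 0] -= fmag * dx
            forces[j, 1] -= fmag * dy
    # half-harmonic restraint on distance from cluster centroid
    cx = pos[:, 0].mean()
    cy = pos[:, 1].mean()
    for i in range(7):
        dx = pos[i, 0] - cx
        dy = pos[i, 1] - cy
        d = np.sqrt(dx * dx + dy * dy)
        if d > r_restraint:
            f = -k_restraint * (d - r_restraint) / d
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
    return forces


@njit(cache=True)
def _run_lj7(n_steps, dt, kT, gamma, stride, seed, pos0, k_restraint, r_restraint):
    np.random.seed(seed)
    n_frames = n_steps // stride
    out = np.empty((n_frames, 7, 2))
    pos = pos0.copy()
    vel = np.zeros((7, 2))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    f = _lj7_forces_jit(pos, k_restraint, r_restraint)
    k = 0
    for step in range(n_steps):
        vel += 0.5 * dt * f
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * np.random.standard_normal((7, 2))
        pos += 0.5 * dt * vel
        f = _lj7_forces_jit(pos, k_restraint, r_restraint)
        vel += 0.5 * dt * f
        if (step + 1) % stride == 0:
            out[k] = pos
            k += 1
        for i in range(7):
            dx = pos[i, 0] - pos[:, 0].mean()
            dy = pos[i, 1] - pos[:, 1].mean()
            if dx * dx + dy * dy > 64.0:
                return out[:0], step
    return out, -1


def hexagonal_minimum() -> np.ndarray:
    """Hexagon configuration (center + 6-ring) near the LJ pair distance."""
    r0 = 2.0 ** (1.0 / 6.0)
    ang = np.arange(6) * np.pi / 3.0
    ring = np.c_[r0 * np.cos(ang), r0 * np.sin(ang)]
    return np.vstack([[0.0, 0.0], ring])


def simulate_lj7(protocol: SimulationProtocol, start: np.ndarray = None,
                 k_restraint: float = 5.0, r_restraint: float = 3.0) -> FeatureTrajectory:
    """Langevin-thermostatted LJ7 run.

    Descriptors are the sorted per-particle coordination numbers; the raw
    coordinates are kept on the trajectory for backmapping.  A weak
    half-harmonic restraint beyond `r_restraint` from the centroid prevents
    evaporation at the highest temperatures.
    """
    pos0 = hexagonal_minimum() if start is None else np.asarray(start, float).reshape(7, 2)
    coords, failed = _run_lj7(
        protocol.n_steps, protocol.dt, protocol.kT, protocol.gamma,
        protocol.stride, protocol.seed, pos0, k_restraint, r_restraint,
    )
    if failed >= 0:
        raise FloatingPointError(
            f"particle escaped beyond the restraint at step {failed}; "
            "use a stronger restraint (larger k_restraint)"
        )
    cn = coordination_numbers(coords)
    feats = np.sort(cn, axis=1)
    return FeatureTrajectory(feats, frame_interval=protocol.frame_interval,
                             temperature_tag=protocol.kT, coords=coords)


def coordination_numbers(coords: np.ndarray, r0: float = 1.5) -> np.ndarray:
    """Smooth per-particle coordination numbers.

    c_i = sum_j (1 - (r_ij/r0)^8) / (1 - (r_ij/r0)^16), the standard smooth
    switching function with r0 = 1.5 sigma.
    """
    c = np.asarray(coords, dtype=float)
    single = c.ndim == 2
    c = c.reshape(-1, 7, 2)
    diff = c[:, :, None, :] - c[:, None, :, :]
    r = np.sqrt((diff**2).sum(-1))
    x = r / r0
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (1.0 - x**8) / (1.0 - x**16)
    # remove self terms; the switching function limit at r = r0 is 1/2
    s[np.isnan(s) & (r > 0)] = 0.5
    idx = np.arange(7)
    s[:, idx, idx] = 0.0
    cn = s.sum(axis=2)
    return cn[0] if single else cn


def coordination_moments(c: np.ndarray):
    """Second and third central moments of 7 coordination numbers."""
    c = np.asarray(c, dtype=float)
    single = c.ndim == 1
    c = np.atleast_2d(c)
    if c.shape[1] != 7:
        raise ValueError("expected 7 coordination numbers per frame")
    dev = c - c.mean(axis=1, keepdims=True)
    mu2 = (dev**2).mean(axis=1)
    mu3 = (dev**3).mean(axis=1)
    if single:
        return float(mu2[0]), float(mu3[0])
    return mu2, mu3
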