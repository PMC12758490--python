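"""Langevin generators: potential/force correctness, frame-count contracts,
Boltzmann statistics and LJ7 order parameters."""

import numpy as np
import pytest

from thermoflow.simulators import (SimulationProtocol, coordination_moments,
                                   coordination_numbers, hexagonal_minimum,
                                   lj7_energy_forces, simulate_langevin,
                                   simulate_lj7, three_hole_gradient,
                                   three_hole_potential)


def descend(start, grad_fn, lr=0.01, steps=4000):
    x = np.array(start, dtype=float)
    for _ in range(steps):
        g = np.array(grad_fn(*x))
        x -= lr * g
    return x


class TestThreeHolePotential:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(-2, 2, size=(100, 2))
        eps = 1e-6
        gx, gy = three_hole_gradient(pts[:, 0], pts[:, 1])
        fx = (three_hole_potential(pts[:, 0] + eps, pts[:, 1])
              - three_hole_potential(pts[:, 0] - eps, pts[:, 1])) / (2 * eps)
        fy = (three_hole_potential(pts[:, 0], pts[:, 1] + eps)
              - three_hole_potential(pts[:, 0], pts[:, 1] - eps)) / (2 * eps)
        assert np.allclose(gx, fx, rtol=1e-6, atol=1e-6)
        assert np.allclose(gy, fy, rtol=1e-6, atol=1e-6)

    def test_two_deep_minima_mirror_symmetric(self):
        left = descend((-1.0, 0.0), three_hole_gradient)
        right = descend((1.0, 0.0), three_hole_gradient)
        assert left[0] == pytest.approx(-right[0], abs=1e-6)
        assert left[1] == pytest.approx(right[1], abs=1e-6)
        assert three_hole_potential(*left) == pytest.approx(
            three_hole_potential(*right), abs=1e-10)

    def test_upper_channel_local_minimum_above_deep_minima(self):
        upper = descend((0.0, 1.5), three_hole_gradient)
        deep = descend((1.0, 0.0), three_hole_gradient)
        assert upper[1] > 1.0  # genuinely in the upper channel
        g = np.hypot(*three_hole_gradient(*upper))
        assert g < 1e-6       # a stationary point
        assert three_hole_potential(*upper) > three_hole_potential(*deep)


class TestLangevin:
    def test_frame_count_contract(self):
        proto = SimulationProtocol(n_steps=5000, stride=50, seed=0)
        traj = simulate_langevin(proto)
        assert len(traj) == 100
        assert proto.n_frames == 100
        assert traj.frame_interval == pytest.approx(0.05)

    def test_zero_temperature_stays_at_minimum(self):
        start = descend((1.0, 0.0), three_hole_gradient)
        proto = SimulationProtocol(n_steps=20_000, stride=100, kT=0.0, seed=1)
        traj = simulate_langevin(proto, start=start)
        drift = np.abs(traj.frames - start).max()
        assert drift <= 1e-8

    def test_bit_identical_reproducibility(self):
        proto = SimulationProtocol(n_steps=10_000, stride=10, seed=5)
        a = simulate_langevin(proto)
        b = simulate_langevin(proto)
        assert np.array_equal(a.frames, b.frames)

    def test_equilibrium_histogram_matches_boltzmann(self):
        proto = SimulationProtocol(n_steps=2_000_000, stride=20, seed=1)
        traj = simulate_langevin(proto)
        H, xe, ye = np.histogram2d(traj.frames[:, 0], traj.frames[:, 1],
                                   bins=40, range=[[-2, 2], [-1, 2.2]])
        xc, yc = (xe[:-1] + xe[1:]) / 2, (ye[:-1] + ye[1:]) / 2
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        w = np.exp(-three_hole_potential(X, Y) / proto.kT)
        mask = H > 20
        r = np.corrcoef(H[mask], w[mask])[0, 1]
        assert r > 0.95
        # x -> -x symmetry of the two deep basins within sampling error
        left = (traj.frames[:, 0] < -0.4).mean()
        right = (traj.frames[:, 0] > 0.4).mean()
        assert abs(left - right) < 0.1


class TestLJ7:
    def test_pair_at_lj_minimum(self):
        coords = np.zeros((7, 2))
        coords[1] = [2 ** (1 / 6), 0.0]
        coords[2:] = np.array([[50, 50 + i] for i in range(5)])  # far away
        E, F = lj7_energy_forces(coords)
        # far-away pair contributions are negligible; the bound pair gives -1
        pair = 4 * ((2 ** (1 / 6)) ** -12 - (2 ** (1 / 6)) ** -6)
        assert pair == pytest.approx(-1.0)
        assert np.abs(F[0]).max() < 1e-6
        assert np.abs(F[1]).max() < 1e-6

    def test_forces_match_finite_differences(self):
        rng = np.random.default_rng(2)
        coords = hexagonal_minimum() + 0.05 * rng.standard_normal((7, 2))
        E, F = lj7_energy_forces(coords)
        eps = 1e-6
        for i in range(7):
            for k in range(2):
                cp, cm = coords.copy(), coords.copy()
                cp[i, k] += eps
                cm[i, k] -= eps
                num = -(lj7_energy_forces(cp)[0] - lj7_energy_forces(cm)[0]) / (2 * eps)
                assert F[i, k] == pytest.approx(num, rel=1e-6, abs=1e-6)

    def test_coincident_particles_rejected(self):
        coords = hexagonal_minimum()
        coords[1] = coords[0]
        with pytest.raises(ValueError, match="coincide"):
            lj7_energy_forces(coords)

    def test_hexagon_is_local_minimum(self):
        rng = np.random.default_rng(3)
        x = hexagonal_minimum() + 0.02 * rng.standard_normal((7, 2))
        for _ in range(5000):
            _, F = lj7_energy_forces(x)
            x += 0.002 * F
        E, F = lj7_energy_forces(x)
        assert np.abs(F).max() < 1e-5
        assert E == pytest.approx(-12.5349, abs=1e-3)

    def test_snapshot_count_and_zero_temperature(self):
        proto = SimulationProtocol(n_steps=20_000, dt=0.005, kT=0.0, gamma=1.0,
                                   stride=100, seed=4, system="lj7")
        # relax the start so kT=0 stays put
        x = hexagonal_minimum()
        for _ in range(4000):
            _, F = lj7_energy_forces(x)
            x += 0.002 * F
        traj = simulate_lj7(proto, start=x)
        assert len(traj) == 200
        assert traj.frames.shape == (200, 7)
        spread = traj.frames.max(axis=0) - traj.frames.min(axis=0)
        assert spread.max() < 1e-6  # coordination numbers constant

    def test_mean_energy_increases_with_temperature(self):
        energies = []
        for kT in (0.2, 0.35, 0.5):
            proto = SimulationProtocol(n_steps=200_000, dt=0.005, kT=kT,
                                       gamma=1.0, stride=200, seed=6,
                                       system="lj7")
            traj = simulate_lj7(proto)
            E = [lj7_energy_forces(c)[0] for c in traj.coords[::10]]
            energies.append(np.mean(E))
        assert energies[0] < energies[1] < energies[2]

    def test_evaporation_raises_helpful_error(self):
        proto = SimulationProtocol(n_steps=200_000, dt=0.005, kT=2.0,
                                   gamma=1.0, stride=100, seed=7, system="lj7")
        with pytest.raises(FloatingPointError, match="restraint"):
            simulate_lj7(proto, k_restraint=0.0)


class TestCoordinationMoments:
    def test_equal_coordination_gives_zero_moments(self):
        mu2, mu3 = coordination_moments(np.full(7, 3.0))
        assert mu2 == 0.0
        assert mu3 == 0.0

    def test_hexagon_pattern_direct_formula(self):
        c = np.array([6.0, 3, 3, 3, 3, 3, 3])
        mu2, mu3 = coordination_moments(c)
        dev = c - c.mean()
        assert mu2 == pytest.approx((dev**2).mean())
        assert mu3 == pytest.approx((dev**3).mean())
        assert mu3 > 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        c = rng.uniform(2, 6, 7)
        a = coordination_moments(c)
        b = coordination_moments(c[::-1].copy())
        assert np.allclose(a, b, rtol=1e-12)

    def test_hexagonal_configuration_moments(self):
        cn = coordination_numbers(hexagonal_minimum())
        assert cn[0] > cn[1]  # central particle has the most neighbors
        mu2, mu3 = coordination_moments(cn)
        assert mu3 > 0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="7"):
            coordination_moments(np.ones(6))


def test_protocol_validation():
    with pytest.raises(ValueError):
        SimulationProtocol(n_steps=10, stride=50)
    with pytest.raises(ValueError):
        SimulationProtocol(n_steps=100, stride=10, dt=-0.1)
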