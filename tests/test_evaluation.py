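"""Histogram densities, symmetric KL, free-energy surfaces and MSM/GMRQ
diagnostics, each pinned against closed forms or constructed sequences."""

import numpy as np
import pytest

from thermoflow.evaluation import (Histogram2D, build_msm, fes, gmrq,
                                   histogram_density, implied_timescales,
                                   state_populations, symmetric_kl)


class TestHistogram:
    def test_single_point_occupies_one_bin(self):
        ref = np.array([[0.0, 0.0], [1.0, 1.0]])
        h = histogram_density(np.array([[0.5, 0.5]]), ref)
        p = h.probabilities
        assert p.max() > 0.9              # nearly all mass in one bin
        assert p.min() >= h.epsilon * 0.9  # every other bin at the floor
        assert p.sum() == pytest.approx(1.0)

    def test_uniform_points_near_uniform_probabilities(self):
        g = np.linspace(0, 1, 200)
        pts = np.array(np.meshgrid(g, g)).reshape(2, -1).T
        h = histogram_density(pts, pts)
        assert h.probabilities.std() / h.probabilities.mean() < 0.1

    def test_out_of_range_points_clipped_into_edge_bins(self):
        ref = np.random.default_rng(0).uniform(size=(1000, 2))
        far = np.array([[10.0, 10.0], [-5.0, 0.5]])
        h = histogram_density(np.vstack([ref, far]), ref)
        # counts conserved: all mass accounted for after flooring
        assert h.probabilities.sum() == pytest.approx(1.0)
        assert h.probabilities[-1, -1] > h.epsilon  # clipped corner point

    def test_degenerate_axis_rejected(self):
        ref = np.zeros((10, 2))
        ref[:, 1] = np.arange(10)
        with pytest.raises(ValueError, match="degenerate"):
            histogram_density(ref, ref)

    def test_hundred_bins_from_reference_min_max(self):
        ref = np.random.default_rng(1).uniform(-3, 7, size=(500, 2))
        h = histogram_density(ref, ref)
        assert len(h.edges_x) == 101
        assert h.edges_x[0] == ref[:, 0].min()
        assert h.edges_x[-1] == ref[:, 0].max()


class TestSymmetricKL:
    def _toy(self, p00):
        p = np.full((2, 2), 1e-5)
        p[0, 0] = p00
        p[1, 1] = 1 - p00 - 2e-5
        e = np.array([0.0, 0.5, 1.0])
        return Histogram2D(e, e, p)

    def test_identical_histograms_give_zero(self):
        P = self._toy(0.3)
        assert symmetric_kl(P, P) == 0.0

    def test_two_bin_hand_formula(self):
        P, Q = self._toy(0.3), self._toy(0.6)
        p, q = P.probabilities, Q.probabilities
        expected = float(np.sum(p * np.log(p / q) + q * np.log(q / p)))
        assert symmetric_kl(P, Q) == pytest.approx(expected, abs=1e-15)
        assert symmetric_kl(P, Q) > 0

    def test_symmetry(self):
        P, Q = self._toy(0.2), self._toy(0.7)
        assert symmetric_kl(P, Q) == pytest.approx(symmetric_kl(Q, P))

    def test_binning_mismatch_rejected(self):
        P = self._toy(0.3)
        e = np.array([0.0, 0.6, 1.0])
        Q = Histogram2D(e, e, P.probabilities)
        with pytest.raises(ValueError, match="binning"):
            symmetric_kl(P, Q)


class TestFES:
    def test_uniform_histogram_is_flat_zero(self):
        p = np.full((4, 4), 1 / 16)
        e = np.linspace(0, 1, 5)
        F = fes(Histogram2D(e, e, p), kT=1.0)
        assert np.allclose(F, 0.0)

    def test_relative_depth_is_kT_exactly(self):
        p = np.array([[np.e, 1.0]]) / (np.e + 1)
        e2 = np.array([0.0, 1.0])
        e1 = np.array([0.0, 0.5, 1.0])
        F = fes(Histogram2D(e1, e2, p), kT=2.0)
        assert F.min() == 0.0
        assert F[0, 1] - F[0, 0] == pytest.approx(2.0)

    def test_differences_invariant_to_normalization(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 1, (5, 5))
        e = np.linspace(0, 1, 6)
        F1 = fes(Histogram2D(e, e, p / p.sum()))
        F2 = fes(Histogram2D(e, e, 3.7 * p / p.sum()))
        assert np.allclose(F1 - F1[0, 0], F2 - F2[0, 0])


class TestMSM:
    def test_strict_alternation(self):
        labels = np.tile([0, 1], 500)
        msm = build_msm(labels, lag=1)
        assert np.allclose(msm.transition_matrix, [[0, 1], [1, 0]])
        assert np.allclose(sorted(msm.eigenvalues), [-1, 1])
        assert np.allclose(msm.stationary_distribution, [0.5, 0.5])

    def test_iid_labels_have_no_slow_process(self):
        labels = np.random.default_rng(3).integers(0, 2, 100_000)
        msm = build_msm(labels, lag=1)
        off = msm.transition_matrix[0, 1]
        assert off == pytest.approx(0.5, abs=0.02)
        assert abs(msm.eigenvalues[1]) < 0.02

    def test_block_trajectory_is_nearly_absorbing(self):
        labels = np.r_[np.zeros(10_000, int), np.ones(10_000, int)]
        msm = build_msm(labels, lag=1)
        assert msm.transition_matrix[0, 0] > 0.999
        assert msm.eigenvalues[1] > 0.999

    def test_rows_sum_to_one_and_spectrum_bounded(self):
        labels = np.random.default_rng(4).integers(0, 4, 5000)
        msm = build_msm(labels, lag=3)
        assert np.allclose(msm.transition_matrix.sum(axis=1), 1.0)
        assert msm.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert (msm.eigenvalues >= -1 - 1e-12).all()

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            build_msm(np.zeros(100, int), lag=1)

    def test_segment_bounds_respected(self):
        # two segments whose concatenation would fake a 0->1 transition
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        msm = build_msm(labels, lag=1, segment_bounds=[0, 50, 100])
        assert msm.transition_matrix[0, 1] == 0.0


class TestImpliedTimescales:
    def test_closed_form_value(self):
        msm = build_msm(np.tile([0, 0, 1, 1], 1000), lag=1)
        msm.eigenvalues = np.array([1.0, 0.8])
        t = implied_timescales(msm, lag=1, frame_interval=1.0)
        assert t[0] == pytest.approx(-1 / np.log(0.8), abs=1e-10)
        assert t[0] == pytest.approx(4.4814, abs=1e-3)

    def test_unit_eigenvalue_gives_infinity(self):
        msm = build_msm(np.tile([0, 1], 100), lag=1)
        msm.eigenvalues = np.array([1.0, 1.0, -0.5])
        t = implied_timescales(msm, lag=2, frame_interval=0.5)
        assert np.isinf(t[0])
        assert len(t) == 1  # negative eigenvalue skipped

    def test_reciprocal_eigenvalue_gives_lag_interval(self):
        msm = build_msm(np.tile([0, 1], 100), lag=1)
        msm.eigenvalues = np.array([1.0, np.exp(-1.0)])
        t = implied_timescales(msm, lag=7, frame_interval=0.2)
        assert t[0] == pytest.approx(7 * 0.2)


class TestGMRQ:
    def test_perfectly_metastable_blocks_score_two(self):
        labels = np.r_[np.zeros(10_000, int), np.ones(10_000, int)]
        assert gmrq(labels, lag=1) == pytest.approx(2.0, abs=1e-3)

    def test_iid_labels_score_one(self):
        labels = np.random.default_rng(5).integers(0, 2, 200_000)
        assert gmrq(labels, lag=1) == pytest.approx(1.0, abs=0.02)

    def test_never_exceeds_state_count(self):
        labels = np.random.default_rng(6).integers(0, 3, 10_000)
        assert gmrq(labels, lag=2) <= 3.0 + 1e-12


class TestStatePopulations:
    def test_simple_fractions(self):
        assert np.allclose(state_populations([0, 0, 1]), [2 / 3, 1 / 3])

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(0, 3, 1000)
        shuffled = rng.permutation(labels)
        assert np.allclose(state_populations(labels), state_populations(shuffled))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            state_populations([])
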