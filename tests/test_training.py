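"""Lagged-pair construction, temperature rescaling, the unified loss and
its reduction to the standard-Gaussian IB objective, and fold handling."""

import numpy as np
import pytest

from thermoflow.autodiff import Tensor
from thermoflow.data import FeatureTrajectory
from thermoflow.flow import RealNVP
from thermoflow.spib import EncoderDecoder
from thermoflow.training import (TrainConfig, make_lagged_pairs, select_tau,
                                 split_folds, temperature_scale, unified_loss)

_LOG_2PI = np.log(2 * np.pi)


class TestLaggedPairs:
    def test_single_segment_count(self):
        traj = FeatureTrajectory(np.zeros((100, 1)))
        pairs = make_lagged_pairs(traj, 10)
        assert len(pairs) == 90
        assert np.array_equal(pairs[0], [0, 10])
        assert np.array_equal(pairs[-1], [89, 99])

    def test_pairs_never_cross_segment_boundary(self):
        traj = FeatureTrajectory(np.zeros((100, 1)), segment_bounds=[0, 50, 100])
        pairs = make_lagged_pairs(traj, 10)
        assert len(pairs) == 80
        # no pair starts before a boundary and ends after it
        assert not np.any((pairs[:, 0] < 50) & (pairs[:, 1] >= 50))

    def test_invalid_lags_rejected(self):
        traj = FeatureTrajectory(np.zeros((20, 1)))
        with pytest.raises(ValueError):
            make_lagged_pairs(traj, 0)
        with pytest.raises(ValueError, match="segment length"):
            make_lagged_pairs(traj, 20)


class TestTemperatureScale:
    @pytest.mark.parametrize("temps,expected", [
        ([340, 440], [1.0, 440 / 340]),
        ([0.2, 0.5], [1.0, 2.5]),
        ([300], [1.0]),
        ([0.5, 0.2, 0.7], [2.5, 1.0, 3.5]),
    ])
    def test_rescaling_rule(self, temps, expected):
        assert np.allclose(temperature_scale(temps), expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            temperature_scale([])
        with pytest.raises(ValueError):
            temperature_scale([300, -10])


class TestUnifiedLoss:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.X = rng.standard_normal((32, 3))
        self.y = rng.integers(0, 4, 32)
        self.eps = rng.standard_normal((32, 2))
        self.net = EncoderDecoder(3, 4, sigma0=0.2, seed=1)
        self.T = np.ones(32)

    def test_identity_flow_zero_tilt_reduces_to_gaussian_ib(self):
        """With a fresh (identity) flow and tau=0 the regularizer is exactly
        log N(u; mu, sigma^2 I) - log N(u; 0, I)."""
        flow = RealNVP(seed=2)  # identity at init
        beta = 0.01
        loss, _ = unified_loss(self.X, self.y, self.T, self.net, flow,
                               tau=0.0, beta=beta, eps=self.eps)
        # reference computed directly in numpy
        mu = self.net.encode(self.X)
        sigma = self.net.sigma
        u = mu + sigma * self.eps
        logits = self.net.decode(u)
        ce = -np.log(logits[np.arange(32), self.y]).mean()
        log_q = (-2 * np.log(sigma) - 0.5 * (self.eps**2).sum(1) - _LOG_2PI).mean()
        log_r = (-0.5 * (u**2).sum(1) - _LOG_2PI).mean()
        expected = ce + beta * (log_q - log_r)
        assert float(loss.data) == pytest.approx(expected, abs=1e-6)

    def test_zero_beta_is_pure_cross_entropy_with_no_flow_gradient(self):
        flow = RealNVP(seed=3)
        loss, comps = unified_loss(self.X, self.y, self.T, self.net, flow,
                                   tau=2.0, beta=0.0, eps=self.eps)
        assert float(loss.data) == pytest.approx(comps["ce"], abs=1e-12)
        loss.backward()
        for p in flow.parameters():
            assert p.grad is None or np.allclose(p.grad, 0.0)

    def test_gradient_matches_finite_differences_on_tiny_batch(self):
        rng = np.random.default_rng(7)
        X, y, T = self.X[:2], self.y[:2], self.T[:2]
        eps = self.eps[:2]
        flow = RealNVP(n_blocks=2, hidden=(8,), seed=4)
        for p in flow.parameters():
            p.data = p.data + 0.2 * rng.standard_normal(p.data.shape)
        params = (self.net.parameters() + flow.parameters())
        loss, _ = unified_loss(X, y, T, self.net, flow, 1.5, 0.05, eps)
        loss.backward()
        grads = [None if p.grad is None else p.grad.copy() for p in params]
        h = 1e-6
        checked = 0
        for p, g in zip(params, grads):
            if g is None:
                continue
            flat = p.data.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[idx]
                flat[idx] = old + h
                lp, _ = unified_loss(X, y, T, self.net, flow, 1.5, 0.05, eps)
                flat[idx] = old - h
                lm, _ = unified_loss(X, y, T, self.net, flow, 1.5, 0.05, eps)
                flat[idx] = old
                num = (float(lp.data) - float(lm.data)) / (2 * h)
                ana = g.reshape(-1)[idx]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked > 20

    def test_nonfinite_loss_reports_components(self):
        flow = RealNVP(seed=5)
        X = self.X.copy()
        X[0, 0] = 1e200  # drives the encoder output non-finite downstream
        with pytest.raises(FloatingPointError, match="ce="):
            unified_loss(X, self.y, self.T, self.net, flow, 0.0, 0.01, self.eps)


class TestConfigAndFolds:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(folds=1)
        with pytest.raises(ValueError):
            TrainConfig(tau_grid=())

    def test_split_folds_cover_trajectory_contiguously(self):
        traj = FeatureTrajectory(np.arange(100, dtype=float)[:, None])
        folds = list(split_folds(traj, 5))
        assert len(folds) == 5
        for i, (train, val) in enumerate(folds):
            assert len(val) == 20
            assert len(train) == 80
            assert val.frames[0, 0] == i * 20
            # training side keeps a boundary at the excision point
            if 0 < i < 4:
                assert len(train.segment_bounds) == 3

    def test_select_tau_degenerate_grid_and_contract(self):
        rng = np.random.default_rng(0)
        # two slow wells in 1-D so a tiny model trains without collapsing
        s = np.cumsum(rng.uniform(size=3000) < 0.01) % 2
        x = np.c_[np.where(s == 0, -1.0, 1.0) + 0.1 * rng.standard_normal(3000)]
        traj = FeatureTrajectory(x)
        fit_kwargs = dict(stage1_cycles=2, stage1_epochs=2, stage2_epochs=1,
                          polish_epochs=2)
        model_kwargs = dict(n_init_states=2, latent_dim=2, beta=0.003,
                            sigma0=0.05)
        tau_opt, table = select_tau(traj, tau_grid=[1.5], lag=5, folds=2,
                                    seed=0, n_generate=2000,
                                    fit_kwargs=fit_kwargs,
                                    model_kwargs=model_kwargs)
        assert tau_opt == 1.5
        assert len(table) == 2
        assert table["ok"].all()
        assert (table["kl"] >= 0).all()

    def test_select_tau_returns_argmin_of_table(self):
        rng = np.random.default_rng(1)
        s = np.cumsum(rng.uniform(size=3000) < 0.01) % 2
        x = np.c_[np.where(s == 0, -1.0, 1.0) + 0.1 * rng.standard_normal(3000)]
        traj = FeatureTrajectory(x)
        tau_opt, table = select_tau(
            traj, tau_grid=[0.0, 2.0], lag=5, folds=2, seed=0,
            n_generate=2000,
            fit_kwargs=dict(stage1_cycles=2, stage1_epochs=2, stage2_epochs=1,
                            polish_epochs=2),
            model_kwargs=dict(n_init_states=2, beta=0.003, sigma0=0.05))
        means = table[table.ok].groupby("tau")["kl"].mean()
        assert tau_opt == means.idxmin()
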