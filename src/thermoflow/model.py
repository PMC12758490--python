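"""Model / Results interface for joint information-bottleneck + flow training.

`ThermoFlowModel` holds the data and hyperparameters; `fit()` runs the
two-step schedule (vanilla state-predictive IB with VampPrior until the state
assignment converges, then joint optimization of encoder, decoder, posterior
scale and coupling flow under the unified loss) and returns a
`ThermoFlowResults` carrying the trained networks, the state assignment, the
training history and everything generative: temperature-steered sampling,
likelihood scoring, state representatives, path interpolation and
nearest-neighbor backmapping.

`SPIBModel` is the vanilla baseline — identical, minus the flow.
"""

from __future__ import annotations

import io as _io
import json

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .data import FeatureTrajectory
from .flow import RealNVP, model_log_likelihood
from .nn import Adam
from .priors import TiltedGaussian
from .spib import (EncoderDecoder, StateAssignment, init_labels,
                   refine_labels, vamp_prior_log_density)
from .training import (TrainConfig, make_lagged_pairs, temperature_scale,
                       unified_loss, vamp_loss)
from . import generation as gen

__all__ = ["ThermoFlowModel", "SPIBModel", "ThermoFlowResults", "SPIBResults"]

_LOG_2PI = float(np.log(2.0 * np.pi))


def _as_traj_list(data):
    if isinstance(data, FeatureTrajectory):
        return [data]
    if isinstance(data, np.ndarray):
        return [FeatureTrajectory(data)]
    return [t if isinstance(t, FeatureTrajectory) else FeatureTrajectory(t)
            for t in data]


class ThermoFlowModel:
    """Joint CV-learning + generative model over time-lagged descriptor data.

    Parameters
    ----------
    data : FeatureTrajectory, array, or list of FeatureTrajectory
        Time-ordered descriptor matrices.  Multi-temperature training passes
        one trajectory per temperature.
    lag : int
        Prediction lag in recorded frames.
    n_init_states : int
        Number of k-means clusters used for the initial state labels.
    tau : float
        Tilting factor of the prior.
    temperatures : sequence, optional
        Physical temperatures per trajectory; rescaled so the lowest is 1.
        Defaults to each trajectory's `temperature_tag`.
    init_features : array, optional
        Alternative space for the initial k-means clustering (e.g. the
        coordination-number moments for the LJ7 cluster), stacked over all
        trajectories in order.
    """

    def __init__(self, data, lag: int = 10, n_init_states: int = 6,
                 tau: float = 2.5, beta: float = 0.01, latent_dim: int = 2,
                 encoder_hidden=(64, 64), decoder_hidden=(64,),
                 flow_blocks: int = 8, flow_hidden=(32, 32), s_max: float = 3.0,
                 sigma0: float = 0.01, temperatures=None, init_features=None,
                 standardize: bool = True):
        self.trajectories = _as_traj_list(data)
        self.lag = int(lag)
        self.n_init_states = int(n_init_states)
        self.tau = float(tau)
        self.beta = float(beta)
        self.latent_dim = int(latent_dim)
        self.encoder_hidden = tuple(encoder_hidden)
        self.decoder_hidden = tuple(decoder_hidden)
        self.flow_blocks = int(flow_blocks)
        self.flow_hidden = tuple(flow_hidden)
        self.s_max = float(s_max)
        self.sigma0 = float(sigma0)
        self.init_features = init_features
        self.standardize = bool(standardize)

        tags = [t.temperature_tag for t in self.trajectories]
        if temperatures is not None:
            self.steerable_T = temperature_scale(temperatures)
        else:
            self.steerable_T = temperature_scale(tags)

        self._X_raw = np.concatenate([t.frames for t in self.trajectories])
        if standardize:
            self._mean = self._X_raw.mean(axis=0)
            self._std = self._X_raw.std(axis=0)
            self._std[self._std < 1e-12] = 1.0
        else:
            self._mean = np.zeros(self._X_raw.shape[1])
            self._std = np.ones(self._X_raw.shape[1])
        self._X = (self._X_raw - self._mean) / self._std

        # global lagged pairs, per-pair steerable temperature
        offset = 0
        pairs, pair_T, frame_T = [], [], []
        for traj, T in zip(self.trajectories, self.steerable_T):
            p = make_lagged_pairs(traj, self.lag) + offset
            pairs.append(p)
            pair_T.append(np.full(len(p), T))
            frame_T.append(np.full(len(traj), T))
            offset += len(traj)
        self._pairs = np.concatenate(pairs)
        self._pair_T = np.concatenate(pair_T)
        self._frame_T = np.concatenate(frame_T)

    # ------------------------------------------------------------------
    @property
    def n_frames(self):
        return len(self._X)

    def _joint(self):
        return True

    def fit(self, seed: int = 0, config: TrainConfig = None, verbose: bool = False,
            init_labels_override: np.ndarray = None, **overrides):
        """Run the two-step schedule and return a results object."""
        cfg = config or TrainConfig(beta=self.beta, lag=self.lag)
        for k, v in overrides.items():
            if not hasattr(cfg, k):
                raise TypeError(f"unknown training option {k!r}")
            setattr(cfg, k, v)
        ss = np.random.SeedSequence(seed)
        seeds = ss.generate_state(6) % (2**31 - 1)
        rng = np.random.default_rng(int(seeds[0]))

        # --- initial labels
        if init_labels_override is not None:
            assign = StateAssignment.from_labels(init_labels_override)
        else:
            feats = self.init_features if self.init_features is not None else self._X
            assign = init_labels(feats, self.n_init_states, seed=int(seeds[1]))
        labels = assign.labels.copy()

        net = EncoderDecoder(self._X.shape[1], assign.n_states,
                             latent_dim=self.latent_dim,
                             encoder_hidden=self.encoder_hidden,
                             decoder_hidden=self.decoder_hidden,
                             sigma0=self.sigma0, seed=int(seeds[2]))
        flow = RealNVP(self.latent_dim, self.flow_blocks, self.flow_hidden,
                       s_max=self.s_max, seed=int(seeds[3]))
        pseudo_idx = rng.choice(self.n_frames, size=cfg.n_pseudo_inputs, replace=False)
        pseudo = Tensor(self._X[pseudo_idx].copy(), requires_grad=True)

        history = []

        # --- stage 1: vanilla IB with VampPrior + iterative relabeling
        opt = Adam(net.parameters() + [pseudo], lr=cfg.lr)
        below_tol = 0
        for cycle in range(cfg.stage1_cycles):
            comps = self._run_epochs(net, flow, pseudo, labels, cfg,
                                     cfg.stage1_epochs, rng, opt, joint=False)
            n_before = net.n_states
            assign, changed, _ = refine_labels(net, self._X, labels, cfg.relabel_tol)
            labels = assign.labels
            if net.n_states != n_before:
                # decoder head shrank: optimizer moments no longer match
                opt = Adam(net.parameters() + [pseudo], lr=cfg.lr)
            history.append({"stage": 1, "cycle": cycle, **comps,
                            "n_states": assign.n_states, "relabeled": changed})
            if verbose:
                print(f"[stage1 {cycle}] loss={comps['loss']:.4f} "
                      f"states={assign.n_states} changed={changed:.4f}")
            if assign.n_states == 1:
                raise RuntimeError(
                    "state assignment collapsed to a single state during "
                    "stage 1; lower beta or the lag, or give more states")
            below_tol = below_tol + 1 if changed < cfg.relabel_tol else 0
            if below_tol >= 2:
                break

        if not self._joint():
            res = self._build_results(net, flow, pseudo, labels, history, cfg, seed)
            return res

        # --- stage 2: joint flow + IB training, labels frozen
        opt = Adam(net.parameters() + flow.parameters(), lr=cfg.lr)
        for epoch in range(cfg.stage2_epochs):
            # step-down learning-rate schedule sharpens the flow fit
            frac = epoch / max(cfg.stage2_epochs, 1)
            opt.lr = cfg.lr * (1.0 if frac < 0.5 else 0.3 if frac < 0.8 else 0.1)
            comps = self._run_epochs(net, flow, pseudo, labels, cfg, 1, rng,
                                     opt, joint=True)
            history.append({"stage": 2, "cycle": epoch, **comps,
                            "n_states": net.n_states, "relabeled": 0.0})
            if verbose and epoch % 10 == 0:
                print(f"[stage2 {epoch}] loss={comps['loss']:.4f}")
        # flow-only polish: encoder and states frozen, the density model
        # converges on a now-stationary latent target
        if cfg.polish_epochs > 0:
            opt = Adam(flow.parameters(), lr=cfg.lr)
            ema = [p.data.copy() for p in flow.parameters()]
            decay = 0.85
            for epoch in range(cfg.polish_epochs):
                frac = epoch / cfg.polish_epochs
                opt.lr = cfg.lr * (1.0 if frac < 0.4 else 0.25 if frac < 0.7 else 0.05)
                comps = self._run_epochs(net, flow, pseudo, labels, cfg, 1, rng,
                                         opt, joint=True, train_ib=False)
                if frac >= 0.4:
                    # Polyak-average the late-stage flow parameters
                    for e, p in zip(ema, flow.parameters()):
                        e *= decay
                        e += (1 - decay) * p.data
                else:
                    for e, p in zip(ema, flow.parameters()):
                        e[...] = p.data
                history.append({"stage": 3, "cycle": epoch, **comps,
                                "n_states": net.n_states, "relabeled": 0.0})
            for e, p in zip(ema, flow.parameters()):
                p.data = e.copy()
        # one final label refresh
        assign, changed, _ = refine_labels(net, self._X, labels, cfg.relabel_tol)
        labels = assign.labels
        history.append({"stage": 2, "cycle": cfg.stage2_epochs,
                        **comps, "n_states": assign.n_states, "relabeled": changed})
        return self._build_results(net, flow, pseudo, labels, history, cfg, seed)

    # ------------------------------------------------------------------
    def _run_epochs(self, net, flow, pseudo, labels, cfg, n_epochs, rng, opt,
                    joint: bool, train_ib: bool = True):
        pairs, pair_T = self._pairs, self._pair_T
        d = self.latent_dim
        if joint:
            uniq = np.unique(pair_T)
            lut = {t: TiltedGaussian(self.tau, d, t).log_Z()
                   + 0.5 * d * (_LOG_2PI + np.log(t)) for t in uniq}
            log_const = np.array([lut[t] for t in pair_T])
        comps = {}
        n = len(pairs)
        for _ in range(n_epochs):
            perm = rng.permutation(n)
            agg, nb = None, 0
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                Xb = self._X[pairs[idx, 0]]
                yb = labels[pairs[idx, 1]]
                eps = rng.standard_normal((len(idx), d))
                if joint and not train_ib:
                    # flow-only maximum likelihood on the frozen encoded means
                    # (the distribution actually compared against at inference,
                    # where encoding is deterministic); a sub-bin smoothing
                    # kernel keeps the density estimate from developing spikes
                    from .flow import flow_log_likelihood_t
                    u = Tensor(net.encode(Xb) + cfg.polish_noise * eps)
                    ll = flow_log_likelihood_t(u, flow, self.tau, pair_T[idx],
                                               log_const[idx]).mean()
                    loss = -ll
                    comps_b = {"loss": float(loss.data), "ce": np.nan,
                               "log_posterior": np.nan,
                               "log_likelihood": float(ll.data)}
                elif joint:
                    loss, comps_b = unified_loss(Xb, yb, pair_T[idx], net, flow,
                                                 self.tau, cfg.beta, eps,
                                                 log_const[idx])
                else:
                    loss, comps_b = vamp_loss(Xb, yb, net, pseudo, cfg.beta, eps)
                loss.backward()
                opt.step()
                agg = comps_b if agg is None else {k: agg[k] + v for k, v in comps_b.items()}
                nb += 1
            comps = {k: v / nb for k, v in agg.items()}
        return comps

    def _build_results(self, net, flow, pseudo, labels, history, cfg, seed):
        assign = StateAssignment.from_labels(labels, compact=False)
        cls = ThermoFlowResults if self._joint() else SPIBResults
        return cls(model=self, net=net, flow=flow, pseudo_inputs=pseudo.data.copy(),
                   assignment=assign, history=pd.DataFrame(history),
                   config=cfg, seed=seed)


class SPIBModel(ThermoFlowModel):
    """Vanilla state-predictive IB baseline with a VampPrior (no flow)."""

    def _joint(self):
        return False


class ThermoFlowResults:
    """Fitted model: networks, state assignment, diagnostics, generation."""

    def __init__(self, model, net, flow, pseudo_inputs, assignment, history,
                 config, seed):
        self.model = model
        self.net = net
        self.flow = flow
        self.pseudo_inputs = pseudo_inputs
        self.assignment = assignment
        self.history = history
        self.config = config
        self.seed = seed
        self.prior = TiltedGaussian(model.tau, model.latent_dim, 1.0)

    # -- core maps -------------------------------------------------------
    def _standardize(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.model._mean) / self.model._std

    def encode(self, X) -> np.ndarray:
        """Latent means mu(X) for raw (unstandardized) descriptor rows."""
        return self.net.encode(self._standardize(X))

    def decode(self, z) -> np.ndarray:
        """State probability vectors for latent points."""
        return self.net.decode(z)

    def predict_states(self, X) -> np.ndarray:
        return self.decode(self.encode(X)).argmax(axis=1)

    @property
    def latent(self) -> np.ndarray:
        """Encoded latent means of all training frames."""
        return self.net.encode(self.model._X)

    @property
    def n_states(self):
        return self.assignment.n_states

    @property
    def sigma(self):
        return self.net.sigma

    # -- generation ------------------------------------------------------
    def generate(self, n: int, temperature: float = 1.0, seed: int = 0,
                 method: str = None, return_labels: bool = False):
        """Sample the prior at the steerable temperature and inverse-flow
        into the IB space; optionally decode state labels."""
        if temperature <= 0:
            raise ValueError("temperature must be > 0")
        spec = self.prior.at_temperature(temperature)
        if method is None:
            method = "radial_icdf" if spec.dim == 2 else "metropolis"
        w = spec.sample(n, seed=seed, method=method)
        z, _ = self.flow.inverse(w)
        if return_labels:
            return z, self.decode(z).argmax(axis=1)
        return z

    def score_frames(self, X=None, temperature: float = 1.0) -> np.ndarray:
        """Exact log-likelihood of each frame's latent mean under flow+prior."""
        mu = self.latent if X is None else self.encode(X)
        return model_log_likelihood(mu, self.flow,
                                    self.prior.at_temperature(temperature))

    def state_representatives(self) -> np.ndarray:
        """Highest-likelihood training frame per state (ties: lowest index)."""
        scores = self.score_frames()
        return gen.state_representatives(scores, self.assignment.labels)

    def interpolate(self, state_a: int, state_b: int, kind: str = "polar_linear",
                    n_waypoints: int = 50, direction: str = "short"):
        """Transition-path interpolation between two states' representatives,
        carried out in the prior space and inverse-flowed to the IB space."""
        reps = self.state_representatives()
        mu = self.latent[[reps[state_a], reps[state_b]]]
        w, _ = self.flow.forward(mu)
        if kind == "slerp":
            path = gen.slerp_path(w[0], w[1], n_waypoints)
        elif kind == "polar_linear":
            path = gen.polar_linear_path(w[0], w[1], n_waypoints, direction=direction)
        else:
            raise ValueError(f"unknown interpolation kind {kind!r}")
        path.waypoints_latent, _ = self.flow.inverse(path.waypoints_prior)
        return path

    def backmap(self, points: np.ndarray, reference: np.ndarray = None) -> np.ndarray:
        """Nearest encoded training frame (Euclidean, IB space) per point."""
        ref = self.latent if reference is None else reference
        return gen.backmap_nearest_neighbor(points, ref)

    # -- plotting --------------------------------------------------------
    def plot_fes(self, points=None, kT: float = 1.0, bins: int = 100, ax=None):
        """Free-energy surface of the latent density, -kT log p shifted to 0.

        `points` defaults to the encoded training frames; pass generated
        samples to plot a generated surface on the same convention.
        """
        import matplotlib.pyplot as plt

        from .evaluation import fes, histogram_density

        pts = self.latent if points is None else np.atleast_2d(points)
        hist = histogram_density(pts, pts, bins=bins)
        F = fes(hist, kT=kT)
        if ax is None:
            _, ax = plt.subplots()
        X, Y = np.meshgrid(hist.edges_x[:-1], hist.edges_y[:-1], indexing="ij")
        m = ax.pcolormesh(X, Y, np.minimum(F, np.percentile(F, 60)),
                          shading="auto")
        ax.figure.colorbar(m, ax=ax, label=f"free energy / kT={kT:g}")
        ax.set_xlabel("latent 1")
        ax.set_ylabel("latent 2")
        return ax

    def plot_history(self, ax=None):
        """Loss components over training epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.history.reset_index(drop=True)
        ax.plot(h.index, h["loss"], label="total loss")
        if h["ce"].notna().any():
            ax.plot(h.index, h["ce"], label="cross-entropy")
        ax.set_xlabel("epoch block")
        ax.set_ylabel("loss")
        ax.legend()
        return ax

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        buf = _io.StringIO()
        with_ce = self.history[self.history["ce"].notna()]
        last = (with_ce if len(with_ce) else self.history).iloc[-1]
        w = buf.write
        w("Joint IB + tilted-prior flow model\n")
        w("=" * 46 + "\n")
        w(f"frames: {self.model.n_frames}   features: {self.model._X.shape[1]}"
          f"   lag: {self.model.lag}\n")
        w(f"latent dim: {self.model.latent_dim}   tilt tau: {self.model.tau}"
          f"   beta: {self.model.beta}\n")
        w(f"steerable temperatures: {np.round(self.model.steerable_T, 4).tolist()}\n")
        w(f"posterior scale sigma: {self.sigma:.4f}\n")
        w(f"states: {self.n_states}   populations: "
          f"{np.round(self.assignment.populations, 4).tolist()}\n")
        w(f"final loss: {last['loss']:.4f}  (cross-entropy {last['ce']:.4f}, "
          f"regularizer {last['loss'] - last['ce']:.4f})\n")
        return buf.getvalue()

    def __repr__(self):
        return (f"<{type(self).__name__}: {self.n_states} states, "
                f"tau={self.model.tau}, {self.model.n_frames} frames>")

    # -- persistence -----------------------------------------------------
    def save(self, path):
        """Checkpoint: all parameters + config in a single npz archive."""
        header = {
            "format": "thermoflow-checkpoint", "version": 1,
            "joint": isinstance(self, ThermoFlowResults) and not isinstance(self, SPIBResults),
            "tau": self.model.tau, "latent_dim": self.model.latent_dim,
            "lag": self.model.lag, "beta": self.model.beta,
            "n_states": int(self.net.n_states),
            "encoder_hidden": list(self.model.encoder_hidden),
            "decoder_hidden": list(self.model.decoder_hidden),
            "flow_blocks": self.model.flow_blocks,
            "flow_hidden": list(self.model.flow_hidden),
            "s_max": self.model.s_max, "seed": int(self.seed),
        }
        arrays = {"mean": self.model._mean, "std": self.model._std,
                  "log_sigma": self.net.log_sigma.data,
                  "pseudo": self.pseudo_inputs,
                  "labels": self.assignment.labels}
        for i, a in enumerate(self.net.encoder.state_arrays()):
            arrays[f"enc_{i}"] = a
        for i, a in enumerate(self.net.decoder.state_arrays()):
            arrays[f"dec_{i}"] = a
        for i, a in enumerate(self.flow.state_arrays()):
            arrays[f"flow_{i}"] = a
        np.savez(path, header=json.dumps(header), **arrays)


class SPIBResults(ThermoFlowResults):
    """Results of the vanilla VampPrior baseline."""

    def generate(self, n: int, temperature: float = 1.0, seed: int = 0,
                 method: str = None, return_labels: bool = False):
        """Sample the VampPrior mixture directly (no flow)."""
        rng = np.random.default_rng(seed)
        mu = self.net.encode(self.pseudo_inputs)
        comp = rng.integers(0, len(mu), size=n)
        z = mu[comp] + self.sigma * rng.standard_normal((n, mu.shape[1]))
        if return_labels:
            return z, self.decode(z).argmax(axis=1)
        return z

    def score_frames(self, X=None, temperature: float = 1.0) -> np.ndarray:
        mu = self.latent if X is None else self.encode(X)
        return vamp_prior_log_density(mu, self.pseudo_inputs, self.net)
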