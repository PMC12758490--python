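"""Training utilities: lagged pairs, the unified loss, temperature rescaling,
fold splitting and tilt-factor selection.

The unified objective for a batch of time-lagged pairs (X_t, y_{t+lag}) is

    L = E[ -log q(y_{t+lag} | u) ]
        + beta * E[ log p(u | X_t) - log r(f(u)) - log|det J_f(u)| ]

with u = mu(X_t) + sigma * eps the reparameterized posterior draw, f the
coupling flow and r the (temperature-steered) tilted prior.  The first term
scores future-state prediction; the remaining terms jointly pull the
flow-transformed posterior onto the prior.  With an identity flow and tau = 0
the regularizer reduces exactly to the standard-Gaussian information
bottleneck objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, softmax_cross_entropy
from .data import FeatureTrajectory
from .flow import RealNVP, flow_log_likelihood_t
from .priors import TiltedGaussian
from .spib import EncoderDecoder, vamp_prior_log_density_t

__all__ = ["TrainConfig", "make_lagged_pairs", "temperature_scale",
           "unified_loss", "select_tau", "split_folds"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class TrainConfig:
    """Hyperparameters of the two-step schedule."""

    beta: float = 0.01
    lag: int = 10
    stage1_cycles: int = 10       # label-refinement cycles (vanilla stage)
    stage1_epochs: int = 3        # epochs per refinement cycle
    stage2_epochs: int = 40       # joint flow + IB epochs
    polish_epochs: int = 15       # flow-only epochs with the encoder frozen
    polish_noise: float = 0.0     # optional kernel-smoothing of the polish target
    batch_size: int = 512
    lr: float = 1e-3
    n_pseudo_inputs: int = 10
    relabel_tol: float = 0.005    # < 0.5% changed frames, twice, to converge
    tau_grid: tuple = tuple(np.arange(0.0, 5.01, 0.5))
    folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("need at least 2 cross-validation folds")
        if len(self.tau_grid) == 0:
            raise ValueError("tau grid must be nonempty")


def make_lagged_pairs(traj, lag: int) -> np.ndarray:
    """Index pairs (t, t+lag) that never cross segment boundaries.

    `traj` may be a FeatureTrajectory or an explicit segment-bounds array.
    Returns an (n_pairs, 2) integer array.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    bounds = traj.segment_bounds if isinstance(traj, FeatureTrajectory) else np.asarray(traj, int)
    pairs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if lag >= b - a:
            raise ValueError(f"lag {lag} >= segment length {b - a}")
        t = np.arange(a, b - lag)
        pairs.append(np.c_[t, t + lag])
    return np.concatenate(pairs, axis=0)


def temperature_scale(temperatures) -> np.ndarray:
    """Steerable parameters: each temperature divided by the lowest one."""
    temps = np.asarray(temperatures, dtype=float)
    if temps.size == 0:
        raise ValueError("temperature list is empty")
    if (temps <= 0).any():
        raise ValueError("temperatures must be positive")
    return temps / temps.min()


def _log_posterior_terms(net: EncoderDecoder, eps: np.ndarray):
    """log p(u|X) at the reparameterized sample: depends only on sigma/eps."""
    d = eps.shape[1]
    const = -0.5 * (eps**2).sum(axis=1) - 0.5 * d * _LOG_2PI
    return net.log_sigma * (-float(d)) + const


def unified_loss(X: np.ndarray, y: np.ndarray, T: np.ndarray,
                 net: EncoderDecoder, flow: RealNVP, tau: float, beta: float,
                 eps: np.ndarray, log_const: np.ndarray = None):
    """Unified joint loss on one batch; returns (Tensor, component dict)."""
    if log_const is None:
        d = net.latent_dim
        log_const = np.array([
            TiltedGaussian(tau, d, t).log_Z() + 0.5 * d * (_LOG_2PI + np.log(t))
            for t in np.atleast_1d(T)
        ])
    mu = net.encoder(Tensor(X))
    u = mu + net.log_sigma.exp() * eps
    ce = softmax_cross_entropy(net.decoder(u), y).mean()
    lq = _log_posterior_terms(net, eps).mean()
    ll = flow_log_likelihood_t(u, flow, tau, T, log_const).mean()
    loss = ce + beta * (lq - ll)
    if not np.isfinite(loss.data):
        raise FloatingPointError(
            f"non-finite loss: ce={ce.data}, log_post={lq.data}, log_lik={ll.data}"
        )
    comps = {"loss": float(loss.data), "ce": float(ce.data),
             "log_posterior": float(lq.data), "log_likelihood": float(ll.data)}
    return loss, comps


def vamp_loss(X: np.ndarray, y: np.ndarray, net: EncoderDecoder,
              pseudo: Tensor, beta: float, eps: np.ndarray):
    """Vanilla objective: cross-entropy + beta * KL-like VampPrior term."""
    mu = net.encoder(Tensor(X))
    u = mu + net.log_sigma.exp() * eps
    ce = softmax_cross_entropy(net.decoder(u), y).mean()
    lq = _log_posterior_terms(net, eps).mean()
    lr_ = vamp_prior_log_density_t(u, pseudo, net).mean()
    loss = ce + beta * (lq - lr_)
    comps = {"loss": float(loss.data), "ce": float(ce.data),
             "log_posterior": float(lq.data), "log_likelihood": float(lr_.data)}
    return loss, comps


# ---------------------------------------------------------------------------
# fold handling and tilt selection
# ---------------------------------------------------------------------------

def split_folds(traj: FeatureTrajectory, folds: int):
    """Contiguous uniform split of one trajectory into `folds` segments.

    Yields (train_trajs, val_traj) per fold; the training side keeps each
    remaining piece as its own segment so no lagged pair spans the cut.
    """
    n = len(traj)
    edges = np.linspace(0, n, folds + 1).astype(int)
    for i in range(folds):
        a, b = edges[i], edges[i + 1]
        train_pieces = []
        for j in range(folds):
            if j == i:
                continue
            ja, jb = edges[j], edges[j + 1]
            train_pieces.append((ja, jb))
        # merge adjacent pieces into contiguous runs
        runs = []
        for ja, jb in train_pieces:
            if runs and runs[-1][1] == ja:
                runs[-1] = (runs[-1][0], jb)
            else:
                runs.append((ja, jb))
        frames = np.concatenate([traj.frames[ja:jb] for ja, jb in runs])
        bounds = np.cumsum([0] + [jb - ja for ja, jb in runs])
        train = FeatureTrajectory(frames, frame_interval=traj.frame_interval,
                                  temperature_tag=traj.temperature_tag,
                                  segment_bounds=bounds)
        val = FeatureTrajectory(traj.frames[a:b].copy(),
                                frame_interval=traj.frame_interval,
                                temperature_tag=traj.temperature_tag)
        yield train, val


def select_tau(data, tau_grid=None, lag: int = 10, folds: int = 5,
               seed: int = 0, n_generate: int = 20000, bins: int = 100,
               fit_kwargs: dict = None, model_kwargs: dict = None):
    """Pick the tilting factor with the lowest cross-validated generation
    divergence.

    For every tau, trains one joint model per fold, generates samples at each
    training temperature, and measures the symmetric KL divergence between the
    generated latent density and the validation-encoded density (averaged over
    training temperatures).  Returns (tau_opt, table) where the table holds
    one row per (tau, fold).  Folds that fail to train are flagged and
    excluded from the argmin.
    """
    from .evaluation import histogram_density, symmetric_kl
    from .model import ThermoFlowModel

    tau_grid = list(tau_grid) if tau_grid is not None else [0.0, 1.0, 2.0, 3.0]
    if len(tau_grid) == 0:
        raise ValueError("tau grid must be nonempty")
    fit_kwargs = dict(fit_kwargs or {})
    model_kwargs = dict(model_kwargs or {})
    trajs = data if isinstance(data, (list, tuple)) else [data]
    rows = []
    rng = np.random.default_rng(seed)
    for tau in tau_grid:
        for fold in range(folds):
            split = [next_fold for next_fold in _nth_fold(trajs, folds, fold)]
            train_list = [s[0] for s in split]
            val_list = [s[1] for s in split]
            fold_seed = int(rng.integers(2**31 - 1))
            try:
                m = ThermoFlowModel(train_list, lag=lag, tau=tau, **model_kwargs)
                res = m.fit(seed=fold_seed, **fit_kwargs)
                kls = []
                for val in val_list:
                    ref = res.encode(val.frames)
                    gen = res.generate(n_generate, temperature=val.temperature_tag,
                                       seed=fold_seed + 1)
                    P = histogram_density(ref, ref, bins=bins)
                    Q = histogram_density(gen, ref, bins=bins)
                    kls.append(symmetric_kl(P, Q))
                rows.append({"tau": tau, "fold": fold, "kl": float(np.mean(kls)),
                             "ok": True})
            except Exception as err:  # noqa: BLE001 - fold failure is data
                warnings.warn(f"tau={tau} fold={fold} failed: {err}")
                rows.append({"tau": tau, "fold": fold, "kl": np.nan, "ok": False})
    table = pd.DataFrame(rows)
    means = table[table["ok"]].groupby("tau")["kl"].mean()
    if means.empty:
        raise RuntimeError("every fold failed; no tau can be selected")
    return float(means.idxmin()), table


def benchmark_folds(traj, tau: float = 2.5, lag: int = 10, folds: int = 5,
                    seed: int = 0, n_generate: int = 100000,
                    model_kwargs: dict = None, baseline_kwargs: dict = None,
                    fit_kwargs: dict = None, baseline_fit_kwargs: dict = None):
    """Five-fold comparison of the joint flow model against the VampPrior
    baseline: generation divergence and GMRQ of the decoded states.

    Returns a DataFrame with one row per fold (kl_joint, kl_vamp,
    gmrq_joint, gmrq_vamp).
    """
    from .evaluation import gmrq, histogram_density, symmetric_kl
    from .model import SPIBModel, ThermoFlowModel

    model_kwargs = dict(model_kwargs or {})
    baseline_kwargs = dict(baseline_kwargs or model_kwargs)
    fit_kwargs = dict(fit_kwargs or {})
    baseline_fit_kwargs = dict(baseline_fit_kwargs or fit_kwargs)
    baseline_fit_kwargs.pop("polish_epochs", None)
    rows = []
    rng = np.random.default_rng(seed)
    for fold, (train, val) in enumerate(split_folds(traj, folds)):
        fs = int(rng.integers(2**31 - 1))
        joint = ThermoFlowModel(train, lag=lag, tau=tau, **model_kwargs).fit(
            seed=fs, **fit_kwargs)
        vamp = SPIBModel(train, lag=lag, **baseline_kwargs).fit(
            seed=fs, **baseline_fit_kwargs)
        row = {"fold": fold}
        for name, res in (("joint", joint), ("vamp", vamp)):
            ref = res.encode(val.frames)
            gen = res.generate(n_generate, seed=fs + 1)
            row[f"kl_{name}"] = symmetric_kl(histogram_density(ref, ref),
                                             histogram_density(gen, ref))
        for name, res in (("joint", joint), ("vamp", vamp)):
            labels = res.predict_states(val.frames)
            try:
                row[f"gmrq_{name}"] = gmrq(labels, lag, n_states=res.n_states)
            except ValueError:
                row[f"gmrq_{name}"] = np.nan  # state missing from the fold
        rows.append(row)
    return pd.DataFrame(rows)


def _nth_fold(trajs, folds, i):
    for traj in trajs:
        gen = split_folds(traj, folds)
        for k, pair in enumerate(gen):
            if k == i:
                yield pair
                break
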