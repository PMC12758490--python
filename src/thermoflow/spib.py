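"""State-predictive information-bottleneck components.

A time-lagged VAE-like model: a Gaussian encoder maps descriptors X_t to a
2-D latent mean mu(X_t) with a single learnable, input-independent posterior
scale sigma; a softmax decoder predicts the metastable state occupied at
t + lag.  States are discovered self-consistently — initial k-means labels
are iteratively refined by relabeling every frame with its most probable
decoded state, which merges short-lived states into long-lived ones.

The vanilla baseline regularizes the encoded distribution towards a
variational mixture of posteriors (VampPrior); the joint flow model replaces
that with a coupling-flow likelihood under the tilted prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .autodiff import Tensor
from .nn import MLP

__all__ = [
    "StateAssignment",
    "EncoderDecoder",
    "init_labels",
    "refine_labels",
    "sample_posterior",
    "vamp_prior_log_density",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class StateAssignment:
    labels: np.ndarray
    n_states: int
    populations: np.ndarray

    @classmethod
    def from_labels(cls, labels: np.ndarray, compact: bool = True) -> "StateAssignment":
        labels = np.asarray(labels, dtype=int)
        uniq, inv = np.unique(labels, return_inverse=True)
        if compact:
            labels = inv
            counts = np.bincount(inv, minlength=len(uniq))
        else:
            counts = np.bincount(labels)
        pops = counts / counts.sum()
        return cls(labels=labels, n_states=len(uniq), populations=pops)


class EncoderDecoder:
    """Encoder mean network + global log-sigma + state decoder."""

    def __init__(self, n_features: int, n_states: int, latent_dim: int = 2,
                 encoder_hidden=(64, 64), decoder_hidden=(64,),
                 sigma0: float = 0.1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.latent_dim = latent_dim
        self.encoder = MLP([n_features, *encoder_hidden, latent_dim], rng,
                           activation="relu")
        self.decoder = MLP([latent_dim, *decoder_hidden, n_states], rng,
                           activation="relu")
        self.log_sigma = Tensor(np.array(np.log(sigma0)), requires_grad=True)

    # numpy inference paths -------------------------------------------------
    @property
    def sigma(self) -> float:
        return float(np.exp(self.log_sigma.data))

    @property
    def n_states(self) -> int:
        return self.decoder.layers[-1].b.data.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        expected = self.encoder.layers[0].W.data.shape[0]
        if X.shape[1] != expected:
            raise ValueError(f"descriptor dimension {X.shape[1]}, encoder expects {expected}")
        return self.encoder.forward_np(X)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        logits = self.decoder.forward_np(z)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def restrict_states(self, keep: np.ndarray):
        """Drop decoder output channels for states that lost all frames."""
        last = self.decoder.layers[-1]
        last.W.data = last.W.data[:, keep].copy()
        last.b.data = last.b.data[keep].copy()

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters() + [self.log_sigma]


def init_labels(features: np.ndarray, k: int, seed: int = 0) -> StateAssignment:
    """Seeded k-means initial state labels on the given feature space."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if k < 2:
        raise ValueError("need at least 2 initial states")
    if k > len(features):
        raise ValueError(f"k={k} exceeds number of frames {len(features)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(features)
    return StateAssignment.from_labels(km.labels_, compact=True)


def sample_posterior(mu: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Reparameterized posterior draw u = mu + sigma * eps."""
    rng = np.random.default_rng(seed)
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    return mu + sigma * rng.standard_normal(mu.shape)


def refine_labels(net: EncoderDecoder, X: np.ndarray, labels: np.ndarray,
                  tol: float = 0.005):
    """One relabeling pass: label := argmax decoder prob of the frame itself.

    Returns (StateAssignment, changed_fraction, keep_index).  Empty states are
    dropped from the decoder head and indices compacted.  A model collapsing
    everything onto one state triggers a warning, not an exception.
    """
    probs = net.decode(net.encode(X))
    new = probs.argmax(axis=1)
    changed = float(np.mean(new != np.asarray(labels)))
    keep = np.unique(new)
    if len(keep) == 1:
        warnings.warn("state assignment collapsed to a single state; "
                      "model is degenerate", RuntimeWarning)
    if len(keep) < probs.shape[1]:
        net.restrict_states(keep)
        remap = -np.ones(probs.shape[1], dtype=int)
        remap[keep] = np.arange(len(keep))
        new = remap[new]
    return StateAssignment.from_labels(new, compact=False), changed, keep


def vamp_prior_log_density(z: np.ndarray, pseudo_inputs: np.ndarray,
                           net: EncoderDecoder) -> np.ndarray:
    """Log-density of the VampPrior: uniform mixture of encoder-conditioned
    Gaussians N(mu(P_k), sigma^2 I) at the pseudo-inputs P_k."""
    pseudo_inputs = np.atleast_2d(pseudo_inputs)
    if len(pseudo_inputs) == 0:
        raise ValueError("VampPrior needs at least one pseudo-input")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    mu = net.encode(pseudo_inputs)
    sigma = net.sigma
    d = z.shape[1]
    d2 = ((z[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
    logp = -0.5 * d2 / sigma**2 - d * np.log(sigma) - 0.5 * d * _LOG_2PI
    m = logp.max(axis=1, keepdims=True)
    return (m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))) - np.log(len(mu))


def vamp_prior_log_density_t(u: Tensor, pseudo: Tensor, net: EncoderDecoder) -> Tensor:
    """Autodiff VampPrior log-density (learnable pseudo-inputs)."""
    mu = net.encoder(pseudo)  # (K, d)
    K = mu.data.shape[0]
    d = mu.data.shape[1]
    ls = net.log_sigma
    inv_var = (ls * (-2.0)).exp()
    # pairwise squared distances via the (u - mu_k)^2 expansion
    u2 = u.square().sum(axis=1).reshape(-1, 1)
    m2 = mu.square().sum(axis=1).reshape(1, -1)
    dots = u @ _transpose(mu)
    d2 = u2 + m2 - dots * 2.0
    logp = d2 * (inv_var * -0.5) - ls * d - 0.5 * d * _LOG_2PI
    return logp.logsumexp(axis=1) - np.log(K)


def _transpose(t: Tensor) -> Tensor:
    out_data = t.data.T
    out = Tensor(out_data, requires_grad=t.requires_grad,
                 parents=(t,) if t.requires_grad else ())
    if t.requires_grad:
        out._backward = lambda g: t._acc(g.T)
    return out
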