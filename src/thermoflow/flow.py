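"""RealNVP coupling flow between the information-bottleneck space and the
prior space.

Each coupling block holds one coordinate channel fixed and updates the other
by an affine map whose scale S and translation T are small tanh networks of
the fixed channel:

    w_a = u_a * exp(S(u_f)) + T(u_f),      w_f = u_f

so the Jacobian is triangular and its log-determinant is just the sum of the
scale outputs.  Masks alternate between blocks; the scale output is squashed
through s_max * tanh(.) for stability, and output layers are zero-initialized
so a fresh flow is exactly the identity.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import MLP
from .priors import TiltedGaussian

__all__ = ["RealNVP", "model_log_likelihood"]

_LOG_2PI = float(np.log(2.0 * np.pi))


class RealNVP:
    def __init__(self, dim: int = 2, n_blocks: int = 8, hidden=(32, 32),
                 s_max: float = 3.0, seed: int = 0):
        if dim < 2:
            raise ValueError("coupling flows need dim >= 2")
        self.dim = dim
        self.n_blocks = n_blocks
        self.s_max = float(s_max)
        rng = np.random.default_rng(seed)
        self.blocks = []
        half = dim // 2
        for i in range(n_blocks):
            if i % 2 == 0:
                fixed = list(range(half))
                update = list(range(half, dim))
            else:
                fixed = list(range(half, dim))
                update = list(range(half))
            s_net = MLP([len(fixed), *hidden, len(update)], rng, zero_init_last=True)
            t_net = MLP([len(fixed), *hidden, len(update)], rng, zero_init_last=True)
            # permutation restoring natural column order from [fixed, update]
            perm = np.argsort(fixed + update)
            self.blocks.append({"fixed": fixed, "update": update,
                                "perm": perm, "s": s_net, "t": t_net})

    # -- parameter plumbing ---------------------------------------------
    def parameters(self):
        out = []
        for blk in self.blocks:
            out.extend(blk["s"].parameters())
            out.extend(blk["t"].parameters())
        return out

    def state_arrays(self):
        out = []
        for blk in self.blocks:
            out.extend(blk["s"].state_arrays())
            out.extend(blk["t"].state_arrays())
        return out

    def load_arrays(self, arrays):
        arrays = list(arrays)
        per_net = len(self.blocks[0]["s"].state_arrays())
        i = 0
        for blk in self.blocks:
            blk["s"].load_arrays(arrays[i:i + per_net]); i += per_net
            blk["t"].load_arrays(arrays[i:i + per_net]); i += per_net

    # -- numpy fast paths ------------------------------------------------
    def _squash(self, raw: np.ndarray) -> np.ndarray:
        # written to match the autodiff path bit-for-bit
        return np.tanh(raw * (1.0 / self.s_max)) * self.s_max

    def forward(self, u: np.ndarray):
        """Map IB-space points to prior space; returns (w, logdet)."""
        x = np.atleast_2d(np.asarray(u, dtype=float)).copy()
        if x.shape[1] != self.dim:
            raise ValueError(f"points have dimension {x.shape[1]}, expected {self.dim}")
        logdet = np.zeros(x.shape[0])
        for k, blk in enumerate(self.blocks):
            xf = x[:, blk["fixed"]]
            s = self._squash(blk["s"].forward_np(xf))
            t = blk["t"].forward_np(xf)
            x[:, blk["update"]] = x[:, blk["update"]] * np.exp(s) + t
            if not np.isfinite(x).all():
                raise FloatingPointError(f"non-finite activation in coupling block {k}")
            logdet += s.sum(axis=1)
        return x, logdet

    def inverse(self, w: np.ndarray):
        """Exact algebraic inverse of forward; returns (u, logdet)."""
        x = np.atleast_2d(np.asarray(w, dtype=float)).copy()
        if x.shape[1] != self.dim:
            raise ValueError(f"points have dimension {x.shape[1]}, expected {self.dim}")
        logdet = np.zeros(x.shape[0])
        for k, blk in enumerate(reversed(self.blocks)):
            xf = x[:, blk["fixed"]]
            s = self._squash(blk["s"].forward_np(xf))
            t = blk["t"].forward_np(xf)
            x[:, blk["update"]] = (x[:, blk["update"]] - t) * np.exp(-s)
            if not np.isfinite(x).all():
                raise FloatingPointError(f"non-finite activation in coupling block {k}")
            logdet -= s.sum(axis=1)
        return x, logdet

    # -- autodiff path (training) ----------------------------------------
    def forward_t(self, u: Tensor):
        x = u
        logdet = None
        inv_smax = 1.0 / self.s_max
        half = self.dim // 2
        for blk in self.blocks:
            lower = blk["fixed"][0] == 0  # fixed channel is the leading block
            a = x.slice_cols(0, half)
            b = x.slice_cols(half, self.dim)
            xf, xa = (a, b) if lower else (b, a)
            s = (blk["s"](xf) * inv_smax).tanh() * self.s_max
            t = blk["t"](xf)
            wa = xa * s.exp() + t
            x = concat([a, wa] if lower else [wa, b], axis=1)
            ld = s.sum(axis=1)
            logdet = ld if logdet is None else logdet + ld
        return x, logdet


def model_log_likelihood(u: np.ndarray, flow: RealNVP, spec: TiltedGaussian) -> np.ndarray:
    """Exact log-likelihood of IB-space points under flow + tilted prior.

    log p(u) = log r(f(u)) + log|det J_f(u)|  by the change of variables.
    """
    w, logdet = flow.forward(u)
    return spec.log_density(w) + logdet


def flow_log_likelihood_t(u: Tensor, flow: RealNVP, tau: float,
                          T: np.ndarray, log_const: np.ndarray) -> Tensor:
    """Autodiff log-likelihood with per-sample steerable temperature.

    `log_const` is the per-sample normalization log Z + (d/2) log(2 pi T),
    precomputed outside the graph (it depends only on tau and T).
    """
    w, logdet = flow.forward_t(u)
    r = w.norm2(axis=1)
    kernel = r.square() * (-0.5 / np.asarray(T, dtype=float)) + r * tau
    return kernel - np.asarray(log_const, dtype=float) + logdet
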