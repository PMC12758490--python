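"""Histogram densities, divergences, free-energy surfaces and Markov state
model diagnostics.

Latent densities are estimated on a fixed 100x100 grid whose edges come from
the reference (simulation/validation) point set; every bin probability is
floored at 1e-5 and renormalized, which keeps KL divergences finite.  MSMs
are estimated from decoder-derived state labels with symmetrized transition
counts (a detailed-balance surrogate), and scored by the generalized matrix
Rayleigh quotient (sum of leading eigenvalues).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .training import make_lagged_pairs

__all__ = ["Histogram2D", "MSMModel", "histogram_density", "symmetric_kl",
           "fes", "build_msm", "implied_timescales", "gmrq",
           "state_populations"]


@dataclass
class Histogram2D:
    edges_x: np.ndarray
    edges_y: np.ndarray
    probabilities: np.ndarray   # (nx, ny), floored and renormalized
    epsilon: float = 1e-5

    def same_binning(self, other: "Histogram2D") -> bool:
        return (np.array_equal(self.edges_x, other.edges_x)
                and np.array_equal(self.edges_y, other.edges_y))


@dataclass
class MSMModel:
    transition_matrix: np.ndarray
    n_states: int
    eigenvalues: np.ndarray          # sorted descending
    stationary_distribution: np.ndarray
    lag: int = 1


def histogram_density(points: np.ndarray, reference_points: np.ndarray,
                      bins: int = 100, epsilon: float = 1e-5) -> Histogram2D:
    """Floored, normalized 2-D histogram on edges set by the reference set.

    Out-of-range points are clipped into the edge bins so counts are
    conserved.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if len(pts) < 1:
        raise ValueError("need at least one point")
    lo, hi = ref.min(axis=0), ref.max(axis=0)
    if np.any(hi - lo <= 0):
        ax = int(np.argmax(hi - lo <= 0))
        raise ValueError(f"degenerate reference axis {ax}: min == max")
    ex = np.linspace(lo[0], hi[0], bins + 1)
    ey = np.linspace(lo[1], hi[1], bins + 1)
    clipped = np.clip(pts, lo + 0, hi)  # edge-bin clipping, count conserved
    H, _, _ = np.histogram2d(clipped[:, 0], clipped[:, 1], bins=[ex, ey])
    p = H / H.sum()
    p = np.maximum(p, epsilon)
    p /= p.sum()
    return Histogram2D(ex, ey, p, epsilon)


def symmetric_kl(P: Histogram2D, Q: Histogram2D) -> float:
    """KL(P||Q) + KL(Q||P) over the floored bin probabilities."""
    if not P.same_binning(Q):
        raise ValueError("histograms use different binning")
    p, q = P.probabilities, Q.probabilities
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def fes(hist: Histogram2D, kT: float = 1.0) -> np.ndarray:
    """Free-energy grid -kT log p, shifted so the minimum is zero."""
    F = -kT * np.log(hist.probabilities)
    return F - F.min()


def build_msm(labels: np.ndarray, lag: int, segment_bounds=None,
              n_states: int = None) -> MSMModel:
    """Symmetrized-count MSM at the given lag from a state-label sequence."""
    labels = np.asarray(labels, dtype=int)
    if segment_bounds is None:
        segment_bounds = np.array([0, len(labels)])
    pairs = make_lagged_pairs(np.asarray(segment_bounds, int), lag)
    k = n_states if n_states is not None else labels.max() + 1
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least 2 states present to build an MSM")
    C = np.zeros((k, k))
    np.add.at(C, (labels[pairs[:, 0]], labels[pairs[:, 1]]), 1.0)
    S = 0.5 * (C + C.T)
    rows = S.sum(axis=1)
    if np.any(rows == 0):
        empty = np.where(rows == 0)[0]
        raise ValueError(f"states {empty.tolist()} have no transition counts")
    T = S / rows[:, None]
    # T is similar to a symmetric matrix -> real spectrum
    d = np.sqrt(rows)
    sym = S / np.outer(d, d)
    evals = eigh(sym, eigvals_only=True)[::-1]
    evals = np.clip(evals, -1.0, 1.0)
    pi = rows / rows.sum()
    return MSMModel(T, k, evals, pi, lag=lag)


def implied_timescales(msm: MSMModel, lag: int = None,
                       frame_interval: float = 1.0) -> np.ndarray:
    """t_k = -lag * interval / ln(lambda_k) for eigenvalues in (0, 1).

    The trivial leading eigenvalue is skipped; eigenvalues at 1 give inf,
    nonpositive eigenvalues are skipped.
    """
    lag = msm.lag if lag is None else lag
    out = []
    for lam in msm.eigenvalues[1:]:
        if lam >= 1.0:
            out.append(np.inf)
        elif lam > 0.0:
            out.append(-lag * frame_interval / np.log(lam))
    return np.asarray(out)


def gmrq(labels: np.ndarray, lag: int, k: int = None, segment_bounds=None,
         n_states: int = None) -> float:
    """Generalized matrix Rayleigh quotient of a state decomposition.

    Sum of the leading k MSM eigenvalues computed on the given (held-out)
    label sequence; higher is better, bounded above by k.
    """
    msm = build_msm(labels, lag, segment_bounds=segment_bounds, n_states=n_states)
    if k is None:
        k = msm.n_states
    return float(np.sum(msm.eigenvalues[:k]))


def state_populations(labels: np.ndarray, n_states: int = None) -> np.ndarray:
    """Normalized state occupation fractions."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    counts = np.bincount(labels, minlength=n_states or 0)
    return counts / counts.sum()
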