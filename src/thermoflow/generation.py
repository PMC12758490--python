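"""Generation-side utilities: state representatives, prior-space transition
path interpolation and nearest-neighbor backmapping.

Paths are interpolated in the prior space (where the tilted prior arranges
the data on a shell) and inverse-flowed back to the IB space by the caller;
endpoints are the prior-space images of each state's highest-likelihood
representative frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PathInterpolation", "state_representatives", "slerp_path",
           "polar_linear_path", "backmap_nearest_neighbor"]


@dataclass
class PathInterpolation:
    endpoints: np.ndarray            # (2, d) prior-space endpoints
    waypoints_prior: np.ndarray      # (n, d)
    kind: str
    waypoints_latent: np.ndarray = None  # filled after inverse-flowing

    def __len__(self):
        return len(self.waypoints_prior)


def state_representatives(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Index of the highest-scoring frame per state (ties: lowest index)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = []
    for s in range(labels.max() + 1):
        idx = np.where(labels == s)[0]
        if idx.size == 0:
            raise ValueError(f"state {s} has no frames")
        out.append(idx[np.argmax(scores[idx])])
    return np.asarray(out)


def slerp_path(w_a, w_b, n_waypoints: int = 50) -> PathInterpolation:
    """Spherical linear interpolation along the great arc between endpoints."""
    a = np.asarray(w_a, dtype=float)
    b = np.asarray(w_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("slerp endpoints must be nonzero")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    omega = np.arccos(cosang)
    if np.pi - omega < 1e-8:
        raise ValueError("antiparallel endpoints: great arc is undefined")
    t = np.linspace(0.0, 1.0, n_waypoints)
    if omega < 1e-12:
        pts = a[None, :] + t[:, None] * (b - a)[None, :]
    else:
        pts = (np.sin((1 - t) * omega)[:, None] * a[None, :]
               + np.sin(t * omega)[:, None] * b[None, :]) / np.sin(omega)
    return PathInterpolation(np.stack([a, b]), pts, "slerp")


def polar_linear_path(w_a, w_b, n_waypoints: int = 50,
                      direction: str = "short") -> PathInterpolation:
    """Linear interpolation of radius and of polar angle (2-D only).

    `direction="short"` follows the shorter arc between the endpoint angles;
    `direction="long"` goes the other way around, which traverses the
    opposite reaction channel on a shell-shaped prior.
    """
    a = np.asarray(w_a, dtype=float)
    b = np.asarray(w_b, dtype=float)
    if a.shape != (2,) or b.shape != (2,):
        raise ValueError("polar interpolation is defined for 2-D points")
    ra, rb = np.linalg.norm(a), np.linalg.norm(b)
    if ra == 0 or rb == 0:
        raise ValueError("polar interpolation needs nonzero-radius endpoints")
    pa, pb = np.arctan2(a[1], a[0]), np.arctan2(b[1], b[0])
    dphi = np.mod(pb - pa + np.pi, 2 * np.pi) - np.pi  # shorter-arc increment
    if direction == "long":
        dphi = dphi - np.sign(dphi) * 2 * np.pi if dphi != 0 else 2 * np.pi
    elif direction != "short":
        raise ValueError("direction must be 'short' or 'long'")
    t = np.linspace(0.0, 1.0, n_waypoints)
    r = ra + t * (rb - ra)
    phi = pa + t * dphi
    pts = np.c_[r * np.cos(phi), r * np.sin(phi)]
    return PathInterpolation(np.stack([a, b]), pts, "polar_linear")


def backmap_nearest_neighbor(points: np.ndarray, reference: np.ndarray,
                             chunk: int = 256) -> np.ndarray:
    """Euclidean nearest reference index per query point (ties: lowest index)."""
    q = np.atleast_2d(np.asarray(points, dtype=float))
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    if len(ref) == 0:
        raise ValueError("reference set is empty")
    out = np.empty(len(q), dtype=int)
    for start in range(0, len(q), chunk):
        block = q[start:start + chunk]
        d2 = ((block[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
        out[start:start + chunk] = d2.argmin(axis=1)
    return out
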