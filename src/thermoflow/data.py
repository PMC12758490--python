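"""Trajectory container shared by the simulators, trainers and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureTrajectory"]


@dataclass
class FeatureTrajectory:
    """Time-ordered per-frame descriptor matrix.

    frames          : (n, d) float array, one row per recorded frame
    frame_interval  : physical time between rows (dt * stride)
    temperature_tag : steerable temperature parameter of this trajectory
                      (1.0 at the lowest training temperature)
    segment_bounds  : start/stop offsets of contiguous segments,
                      e.g. [0, n1, n] — time-lagged pairs never cross these
    coords          : optional raw coordinates backing each frame
    labels          : optional per-frame integer state labels
    """

    frames: np.ndarray
    frame_interval: float = 1.0
    temperature_tag: float = 1.0
    segment_bounds: np.ndarray = None
    coords: np.ndarray = None
    labels: np.ndarray = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError("frames must be a 2-D (n_frames, n_features) array")
        if not np.isfinite(self.frames).all():
            bad = np.argwhere(~np.isfinite(self.frames))[0]
            raise ValueError(f"non-finite feature at frame {bad[0]}, column {bad[1]}")
        if self.segment_bounds is None:
            self.segment_bounds = np.array([0, len(self.frames)])
        else:
            self.segment_bounds = np.asarray(self.segment_bounds, dtype=int)
            if self.segment_bounds[0] != 0 or self.segment_bounds[-1] != len(self.frames):
                raise ValueError("segment_bounds must start at 0 and end at n_frames")

    def __len__(self):
        return len(self.frames)

    @property
    def n_features(self):
        return self.frames.shape[1]

    def segments(self):
        """Yield (start, stop) pairs of contiguous segments."""
        for a, b in zip(self.segment_bounds[:-1], self.segment_bounds[1:]):
            yield int(a), int(b)
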