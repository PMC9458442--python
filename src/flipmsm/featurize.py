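"""Feature time series and pairwise-distance featurization.

The kinetic analysis operates on a ``FeatureSeries``: a T x d real matrix of
collective coordinates sampled at a fixed frame spacing, possibly formed by
concatenating several independent trajectories.  Segment boundaries are
carried along so that no time-lagged statistic ever pairs frames across two
independent simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import Trajectory


@dataclass
class FeatureSeries:
    """Time-ordered T x d feature matrix with segment bookkeeping."""

    values: np.ndarray
    dt: float = 1.0
    labels: list = None
    segment_starts: list = field(default_factory=lambda: [0])
    column_means: np.ndarray = None  # set by mean_free for inverse transform

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise ValueError("a feature series needs at least two frames")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is None:
            self.labels = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if not self.segment_starts or self.segment_starts[0] != 0:
            raise ValueError("segment_starts must begin with 0")
        if any(b >= c for b, c in zip(self.segment_starts, self.segment_starts[1:])):
            raise ValueError("segment_starts must be strictly increasing")
        if self.segment_starts[-1] >= self.values.shape[0]:
            raise ValueError("segment start beyond data length")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def segments(self):
        """Yield (start, stop) index pairs for each independent segment."""
        bounds = list(self.segment_starts) + [self.n_frames]
        for a, b in zip(bounds[:-1], bounds[1:]):
            yield a, b

    def segment_lengths(self) -> list:
        return [b - a for a, b in self.segments()]

    def with_values(self, values, labels=None) -> "FeatureSeries":
        return replace(self, values=values,
                       labels=labels if labels is not None else None,
                       column_means=None)


def pairwise_distance_features(traj: Trajectory, group_a, group_b) -> FeatureSeries:
    """All inter-group atom-pair distances per frame.

    Column (i, j) — row-major over (group_a, group_b) — holds the distance
    between atom ``group_a[i]`` and atom ``group_b[j]``, in Angstrom.  This is
    the lesion-vs-partner distance featurization used upstream of TICA.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("atom groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("atom groups must be disjoint")
    diff = traj.coords[:, a[:, None], :] - traj.coords[:, b[None, :], :]
    dist = np.linalg.norm(diff, axis=-1)  # (F, |a|, |b|)
    labels = [f"d_{i}_{j}" for i in a for j in b]
    return FeatureSeries(values=dist.reshape(traj.n_frames, -1), dt=traj.dt,
                         labels=labels, segment_starts=list(traj.segment_starts))


def mean_free(fs: FeatureSeries) -> FeatureSeries:
    """Remove the per-column mean (over all frames of all segments).

    The removed means are stored on the result (``column_means``) so the
    transform can be inverted; centering an already-centered series is a
    no-op up to floating point.
    """
    means = fs.values.mean(axis=0)
    out = replace(fs, values=fs.values - means)
    out.column_means = means
    return out
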