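"""Time-lagged independent component analysis (TICA).

Estimates the instantaneous covariance C(0) and the time-lagged covariance
C(tau) of mean-free features r(t),

    C_ij(tau) = < r_i(t) r_j(t + tau) >,   averaged over lagged pairs,

solves the generalized eigenproblem C(tau) U = C(0) U Lambda, and projects
the data onto the leading eigenvectors z(t)^T = r(t)^T U.  The estimator is
symmetrized (reversible): lagged pairs are counted in both time directions,
which guarantees real eigenvalues in [-1, 1] and makes the decomposition
invariant under time reversal.  Dimension selection either takes a fixed m
or the smallest m whose cumulative kinetic variance (sum of squared
eigenvalues) reaches a requested fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .featurize import FeatureSeries, mean_free


@dataclass
class TICAModel:
    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray     # descending
    eigenvectors: np.ndarray    # d x m, columns C0-orthonormal
    n_dropped: int = 0          # rank-deficient directions removed in whitening

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def kinetic_variance_fractions(self) -> np.ndarray:
        """Cumulative fraction of kinetic variance (sum lambda_i^2)."""
        kv = self.eigenvalues**2
        return np.cumsum(kv) / kv.sum()

    def dimension_for_fraction(self, fraction: float) -> int:
        if not 0 < fraction <= 1:
            raise ValueError("variance fraction must lie in (0, 1]")
        if fraction == 1.0:
            return int(np.sum(self.eigenvalues > 0))
        return int(np.searchsorted(self.kinetic_variance_fractions(), fraction) + 1)

    def to_json(self, path):
        payload = {
            "lag": self.lag,
            "mean": self.mean.tolist(),
            "c0": self.c0.tolist(),
            "ctau": self.ctau.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "n_dropped": self.n_dropped,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TICAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(lag=d["lag"], mean=np.array(d["mean"]), c0=np.array(d["c0"]),
                   ctau=np.array(d["ctau"]), eigenvalues=np.array(d["eigenvalues"]),
                   eigenvectors=np.array(d["eigenvectors"]), n_dropped=d["n_dropped"])


def time_lagged_covariances(fs: FeatureSeries, lag: int):
    """Segment-aware symmetrized covariance matrices (C0, Ctau).

    Lagged pairs (t, t+lag) are drawn within each independent segment only
    and normalized by the total number of pairs; the input must already be
    mean-free.  C0 averages the instantaneous second moment over both ends
    of each lagged pair; Ctau is symmetrized as (C + C^T)/2.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    for k, (a, b) in enumerate(fs.segments()):
        if b - a <= lag:
            raise ValueError(
                f"lag {lag} is not shorter than segment {k} (length {b - a})"
            )
    d = fs.n_features
    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    n_pairs = 0
    for a, b in fs.segments():
        head = fs.values[a:b - lag]
        tail = fs.values[a + lag:b]
        c0 += head.T @ head + tail.T @ tail
        ctau += head.T @ tail
        n_pairs += b - a - lag
    c0 /= 2.0 * n_pairs
    ctau = (ctau + ctau.T) / (2.0 * n_pairs)
    return c0, ctau


def solve_tica(c0: np.ndarray, ctau: np.ndarray, epsilon: float = 1e-10):
    """Solve C(tau) U = C(0) U Lambda by whitening with a truncated C0.

    Directions whose C0 eigenvalue falls below ``epsilon * trace(C0)`` are
    dropped (pseudo-inverse square-root whitening); the returned eigenpairs
    are sorted by descending eigenvalue, eigenvectors are C0-orthonormal and
    carry a deterministic sign (largest-magnitude component positive).

    Returns (eigenvalues, eigenvectors, n_dropped).
    """
    c0 = np.asarray(c0, dtype=float)
    ctau = np.asarray(ctau, dtype=float)
    s, v = np.linalg.eigh(c0)
    floor = epsilon * max(np.trace(c0), np.finfo(float).tiny)
    keep = s > floor
    n_dropped = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("C0 has no spectral weight above the regularization floor")
    w = v[:, keep] / np.sqrt(s[keep])            # whitening transform
    m = w.T @ ctau @ w
    lam, q = np.linalg.eigh((m + m.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    u = w @ q[:, order]                          # C0-orthonormal by construction
    # deterministic sign: largest-magnitude component of each vector positive
    for j in range(u.shape[1]):
        k = np.argmax(np.abs(u[:, j]))
        if u[k, j] < 0:
            u[:, j] = -u[:, j]
    return lam, u, n_dropped


def fit_tica(fs: FeatureSeries, lag: int, center: bool = True,
             epsilon: float = 1e-10) -> TICAModel:
    """Center the features, estimate covariances and solve the eigenproblem."""
    mean = fs.values.mean(axis=0)
    centered = mean_free(fs) if center else fs
    c0, ctau = time_lagged_covariances(centered, lag)
    lam, u, n_dropped = solve_tica(c0, ctau, epsilon=epsilon)
    return TICAModel(lag=lag, mean=mean if center else np.zeros(fs.n_features),
                     c0=c0, ctau=ctau, eigenvalues=lam, eigenvectors=u,
                     n_dropped=n_dropped)


def project(fs: FeatureSeries, model: TICAModel, n_dims: int = None,
            variance_fraction: float = None, kinetic_map: bool = False) -> FeatureSeries:
    """Project features onto the leading TICA components.

    Either ``n_dims`` or ``variance_fraction`` selects the dimension m; with
    a fraction, m is the smallest count whose cumulative squared-eigenvalue
    share reaches it.  ``kinetic_map=True`` additionally scales component i
    by its eigenvalue (off by default).
    """
    if fs.n_features != model.mean.shape[0]:
        raise ValueError("feature dimension does not match the fitted model")
    if (n_dims is None) == (variance_fraction is None):
        raise ValueError("specify exactly one of n_dims / variance_fraction")
    m = model.dimension_for_fraction(variance_fraction) if n_dims is None else int(n_dims)
    if not 1 <= m <= model.n_components:
        raise ValueError(f"requested {m} components, model has {model.n_components}")
    u = model.eigenvectors[:, :m]
    z = (fs.values - model.mean) @ u
    if kinetic_map:
        z = z * model.eigenvalues[:m]
    return FeatureSeries(values=z, dt=fs.dt,
                         labels=[f"tic{j + 1}" for j in range(m)],
                         segment_starts=list(fs.segment_starts))
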