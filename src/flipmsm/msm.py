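"""Markov state model estimation and validation.

Microstate clustering (k-means), segment-aware sliding-window transition
counting, restriction to the largest strongly connected set, reversible
maximum-likelihood transition-matrix estimation (detailed-balance fixed
point on symmetric pair weights), implied timescales across lag times,
Chapman-Kolmogorov validation with bootstrap confidence bands, PCCA+
metastable coarse-graining, and free energies from stationary weights,

    dG(S_I) = -kB T ln( sum_{j in S_I} pi_j ),   min-shifted to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal / (mol K)


# ---------------------------------------------------------------------------
# Microstate clustering
# ---------------------------------------------------------------------------

@dataclass
class MicrostateAssignment:
    centers: np.ndarray            # k x m
    labels: np.ndarray             # one integer per frame
    k: int
    segment_starts: list = field(default_factory=lambda: [0])
    inertia: float = 0.0


def kmeans_cluster(fs, k: int, seed: int = 0, max_fit_points: int = None) -> MicrostateAssignment:
    """k-means microstates (k-means++ init, deterministic given seed).

    ``max_fit_points`` optionally fits the centers on an evenly strided
    subsample (every frame is still assigned); useful for very long series.
    """
    if k < 2:
        raise ValueError("need at least 2 microstates")
    x = fs.values
    if x.shape[0] < k:
        raise ValueError("fewer frames than requested clusters")
    fit_x = x
    if max_fit_points is not None and x.shape[0] > max_fit_points:
        stride = int(np.ceil(x.shape[0] / max_fit_points))
        fit_x = x[::stride]
    if np.unique(fit_x, axis=0).shape[0] < k:
        # degenerate duplicated data: jitter the fit copy so k-means++ can
        # seed k distinct centers
        rng = np.random.default_rng(seed)
        scale = 1e-8 * (np.abs(fit_x).max() + 1.0)
        fit_x = fit_x + rng.standard_normal(fit_x.shape) * scale
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    km.fit(fit_x)
    labels = km.predict(x)
    return MicrostateAssignment(centers=km.cluster_centers_, labels=labels, k=k,
                                segment_starts=list(fs.segment_starts),
                                inertia=float(km.inertia_))


# ---------------------------------------------------------------------------
# Counting and connectivity
# ---------------------------------------------------------------------------

def count_transitions(labels, lag: int, segment_starts=(0,), n_states: int = None) -> np.ndarray:
    """Sliding-window transition counts C_ij at the given lag.

    Pairs (t, t+lag) are formed within each segment only.
    """
    labels = np.asarray(labels, dtype=int)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if n_states is None:
        n_states = int(labels.max()) + 1
    bounds = list(segment_starts) + [len(labels)]
    c = np.zeros((n_states, n_states))
    any_pairs = False
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a <= lag:
            continue
        any_pairs = True
        np.add.at(c, (labels[a:b - lag], labels[a + lag:b]), 1.0)
    if not any_pairs:
        raise ValueError(f"lag {lag} is not shorter than any segment")
    return c


def largest_connected_set(c: np.ndarray) -> np.ndarray:
    """States in the largest strongly connected component of the count graph."""
    c = np.asarray(c)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("count matrix must be square")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    n_comp, assign = connected_components(sparse.csr_matrix(c > 0),
                                          directed=True, connection="strong")
    sizes = np.bincount(assign, minlength=n_comp)
    # tie-break deterministically on the smallest component id
    best = int(np.argmax(sizes))
    return np.flatnonzero(assign == best)


# ---------------------------------------------------------------------------
# Reversible maximum-likelihood estimation
# ---------------------------------------------------------------------------

def reversible_mle(c: np.ndarray, tol: float = 1e-10, max_iter: int = 1_000_000):
    """Reversible MLE transition matrix from a count matrix.

    Maximizes prod T_ij^C_ij subject to detailed balance pi_i T_ij =
    pi_j T_ji via the standard self-consistent fixed-point iteration on the
    symmetric pair weights x_ij; converged when the maximum relative change
    of the stationary distribution drops below ``tol``.

    Returns (T, pi).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    csym = c + c.T
    if np.any(c.sum(axis=1) == 0):
        raise ValueError("every state needs at least one outgoing count")
    x = csym.copy()
    ci = c.sum(axis=1)
    mask = csym > 0
    for it in range(max_iter):
        xi = x.sum(axis=1)
        pi_old = xi / xi.sum()
        denom = ci[:, None] / xi[:, None] + ci[None, :] / xi[None, :]
        x_new = np.where(mask, csym / np.where(denom > 0, denom, 1.0), 0.0)
        x = x_new
        xi = x.sum(axis=1)
        pi = xi / xi.sum()
        if np.max(np.abs(pi - pi_old) / np.maximum(pi, 1e-300)) < tol:
            t = x / xi[:, None]
            return t, pi
    raise RuntimeError(
        "reversible MLE did not converge; last residual "
        f"{np.max(np.abs(pi - pi_old) / np.maximum(pi, 1e-300)):.3e}"
    )


@dataclass
class MarkovModel:
    """Reversible MSM over the largest connected set of microstates."""

    lag: int
    counts: np.ndarray             # full k x k counts
    active_set: np.ndarray         # indices into the original microstates
    transition_matrix: np.ndarray  # over active set
    stationary: np.ndarray
    eigenvalues: np.ndarray        # descending, real (reversible)
    right_eigenvectors: np.ndarray
    left_eigenvectors: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.active_set)

    def timescales(self, n: int = None) -> np.ndarray:
        """Implied timescales -lag/ln(lambda_i) for eigenvalues below 1."""
        lam = self.eigenvalues[1:None if n is None else n + 1]
        lam = np.clip(lam, None, 1.0 - 1e-15)
        out = np.full(lam.shape, np.inf)
        pos = lam > 0
        out[pos] = -self.lag / np.log(lam[pos])
        return out


def _spectral(t: np.ndarray, pi: np.ndarray):
    """Real sorted eigendecomposition of a reversible transition matrix."""
    sq = np.sqrt(pi)
    s = (t * sq[:, None]) / sq[None, :]
    lam, q = np.linalg.eigh((s + s.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    q = q[:, order]
    right = q / sq[:, None]
    left = q * sq[:, None]
    # normalize the stationary pair: right_0 = 1, left_0 = pi
    scale = right[:, 0].mean()
    right[:, 0] /= scale
    left[:, 0] *= scale
    return lam, right, left


def estimate_msm(labels, lag: int, segment_starts=(0,), n_states: int = None,
                 tol: float = 1e-10) -> MarkovModel:
    """Counts -> largest connected set -> reversible MLE -> spectral analysis."""
    c = count_transitions(labels, lag, segment_starts, n_states=n_states)
    lcs = largest_connected_set(c)
    csub = c[np.ix_(lcs, lcs)]
    t, pi = reversible_mle(csub, tol=tol)
    lam, right, left = _spectral(t, pi)
    return MarkovModel(lag=lag, counts=c, active_set=lcs, transition_matrix=t,
                       stationary=pi, eigenvalues=lam,
                       right_eigenvectors=right, left_eigenvectors=left)


# ---------------------------------------------------------------------------
# Implied timescales
# ---------------------------------------------------------------------------

def implied_timescales(labels, lags, segment_starts=(0,), n_timescales: int = 5,
                       plateau_rtol: float = 0.2):
    """Implied timescales t_i(tau) = -tau/ln lambda_i(tau) across lag times.

    Returns a dict with the lag list, a (n_lags, n_timescales) array (inf
    where the eigenvalue pinned to 1, NaN where negative/complex eigenvalues
    were excluded), the number of excluded eigenvalues, and a per-lag
    boolean flagging the plateau region (relative change to the previous lag
    below ``plateau_rtol`` for the slowest timescale).
    """
    lags = sorted(int(l) for l in lags)
    if len(lags) < 2:
        raise ValueError("need at least two lag times")
    its = np.full((len(lags), n_timescales), np.nan)
    n_excluded = 0
    for i, lag in enumerate(lags):
        model = estimate_msm(labels, lag, segment_starts)
        lam = model.eigenvalues[1:n_timescales + 1]
        bad = lam <= 0
        n_excluded += int(bad.sum())
        ts = model.timescales(n_timescales)
        ts[bad[:len(ts)]] = np.nan
        its[i, :len(ts)] = ts
    plateau = np.zeros(len(lags), dtype=bool)
    for i in range(1, len(lags)):
        a, b = its[i - 1, 0], its[i, 0]
        if np.isfinite(a) and np.isfinite(b) and abs(b - a) <= plateau_rtol * abs(a):
            plateau[i] = True
    return {"lags": lags, "timescales": its, "n_excluded": n_excluded,
            "plateau": plateau}


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test
# ---------------------------------------------------------------------------

def _set_probabilities(t: np.ndarray, pi: np.ndarray, active: np.ndarray,
                       sets: list, power: int) -> np.ndarray:
    """Set-to-set transition probabilities under T^power.

    Row A: start distribution = pi restricted to A (renormalized), summed
    into each set B.  Sets are given in original microstate indices and are
    intersected with the model's active set.
    """
    tk = np.linalg.matrix_power(t, power)
    pos = {s: i for i, s in enumerate(active)}
    out = np.full((len(sets), len(sets)), np.nan)
    for a_i, a_states in enumerate(sets):
        ia = [pos[s] for s in a_states if s in pos]
        if not ia:
            continue
        w = pi[ia] / pi[ia].sum()
        prop = w @ tk[ia]
        for b_i, b_states in enumerate(sets):
            ib = [pos[s] for s in b_states if s in pos]
            out[a_i, b_i] = prop[ib].sum() if ib else np.nan
    return out


@dataclass
class CKResult:
    factors: list
    predicted: np.ndarray       # (n_factors, M, M)
    estimated: np.ndarray       # (n_factors, M, M)
    band_lower: np.ndarray
    band_upper: np.ndarray
    passed: bool
    confidence: float
    n_truncated_factors: int = 0


def chapman_kolmogorov(labels, lag: int, sets, factors=(1, 2, 4, 8),
                       segment_starts=(0,), n_bootstrap: int = 100,
                       confidence: float = 0.95, seed: int = 0) -> CKResult:
    """Chapman-Kolmogorov test on macrostate sets.

    Predicted: the model estimated at ``lag`` propagated as T(lag)^k and
    coarse-grained onto the sets.  Estimated: a model re-estimated at lag
    k*lag, coarse-grained the same way (k = 1 is exact by construction).

    The pass criterion is a joint test at the requested confidence for the
    whole family of curves: trajectory blocks are bootstrap-resampled, the
    predicted and estimated curves are re-computed on each resample *from
    the same resample* so their difference carries both sources of
    statistical error, and the test passes when every observed
    predicted-estimated difference lies within a Gaussian bootstrap band
    whose per-point level is Bonferroni-adjusted (family-wise error rate
    1 - confidence).  Without the adjustment a perfectly Markovian model
    would fail with probability ~1 - confidence^m over m compared points.
    """
    from scipy.stats import norm

    labels = np.asarray(labels, dtype=int)
    factors = sorted(int(k) for k in factors)
    seg_lengths = np.diff(list(segment_starts) + [len(labels)])
    usable = [k for k in factors if k * lag < seg_lengths.max()]
    n_trunc = len(factors) - len(usable)
    if not usable:
        raise ValueError("every requested factor exceeds the segment lengths")
    factors = usable
    n_states = int(labels.max()) + 1
    sets = [np.asarray(s, dtype=int) for s in sets]

    def curves(lbl, starts, tol):
        m = estimate_msm(lbl, lag, starts, n_states=n_states, tol=tol)
        pred = np.array([_set_probabilities(m.transition_matrix, m.stationary,
                                            m.active_set, sets, k)
                         for k in factors])
        est = np.empty_like(pred)
        for i, k in enumerate(factors):
            if k == 1:
                est[i] = pred[i]
                continue
            mk = estimate_msm(lbl, k * lag, starts, n_states=n_states, tol=tol)
            est[i] = _set_probabilities(mk.transition_matrix, mk.stationary,
                                        mk.active_set, sets, 1)
        return pred, est

    predicted, estimated = curves(labels, segment_starts, 1e-10)

    # bootstrap the predicted-estimated differences over trajectory blocks
    rng = np.random.default_rng(seed)
    block = max(10 * max(factors) * lag // 4, 10 * lag, 100)
    blocks = []
    bounds = list(segment_starts) + [len(labels)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        for s in range(a, b, block):
            if min(b, s + block) - s > max(factors) * lag:
                blocks.append((s, min(b, s + block)))
    diffs = np.full((n_bootstrap,) + predicted.shape, np.nan)
    for r in range(n_bootstrap):
        chosen = rng.integers(0, len(blocks), size=len(blocks))
        lbl = np.concatenate([labels[blocks[j][0]:blocks[j][1]] for j in chosen])
        starts = np.concatenate([[0], np.cumsum(
            [blocks[j][1] - blocks[j][0] for j in chosen])[:-1]])
        try:
            pred_r, est_r = curves(lbl, starts.tolist(), 1e-7)
        except (ValueError, RuntimeError):
            continue
        diffs[r] = est_r - pred_r

    with np.errstate(invalid="ignore"):
        std = np.nanstd(diffs, axis=0, ddof=1)
    m_points = int(np.sum(np.isfinite(estimated) & (np.array(
        [[k > 1] for k in factors]).reshape(-1, 1, 1))))
    alpha = (1.0 - confidence) / max(m_points, 1)
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * std
    lower = predicted - half
    upper = predicted + half
    eps = 1e-9
    with np.errstate(invalid="ignore"):
        inside = np.abs(estimated - predicted) <= half + eps
    inside |= ~np.isfinite(estimated)
    return CKResult(factors=factors, predicted=predicted, estimated=estimated,
                    band_lower=lower, band_upper=upper, passed=bool(inside.all()),
                    confidence=confidence, n_truncated_factors=n_trunc)


# ---------------------------------------------------------------------------
# PCCA+ and macrostate free energies
# ---------------------------------------------------------------------------

@dataclass
class MacrostatePartition:
    memberships: np.ndarray    # k x M, rows sum to 1
    crisp: np.ndarray          # argmax macrostate per microstate
    n_macrostates: int
    weights: np.ndarray        # stationary weight per macrostate
    free_energies: np.ndarray  # kcal/mol, min-shifted
    temperature: float


def _inner_simplex_vertices(x: np.ndarray, m: int) -> np.ndarray:
    """Deterministic furthest-point vertex search on eigenvector rows."""
    n = x.shape[0]
    vertices = np.empty(m, dtype=int)
    # farthest row from the origin
    vertices[0] = int(np.argmax(np.linalg.norm(x, axis=1)))
    y = x - x[vertices[0]]
    for j in range(1, m):
        dist = np.linalg.norm(y, axis=1)
        vertices[j] = int(np.argmax(dist))
        v = y[vertices[j]]
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise ValueError(
                "degenerate eigenvector simplex; reduce the macrostate count"
            )
        y = y - np.outer(y @ v, v) / nv**2
    return vertices


def pcca_plus(model: MarkovModel, m: int) -> "MacrostatePartition":
    """PCCA+ fuzzy memberships from the top-m right eigenvectors.

    Vertex microstates are found deterministically by furthest-point search
    on the eigenvector simplex; memberships are the linear transform mapping
    those vertices to the unit simplex corners, clipped to [0, 1] and row
    renormalized.  Crisp assignment is the argmax.
    """
    k = model.n_states
    if not 2 <= m <= k:
        raise ValueError("macrostate count must lie in [2, n_microstates]")
    if model.eigenvalues[m - 1] <= 0:
        raise ValueError(
            f"only {int(np.sum(model.eigenvalues > 0))} eigenvalues are positive; "
            f"choose a smaller macrostate count than {m}"
        )
    x = model.right_eigenvectors[:, :m].copy()
    x[:, 0] = 1.0
    vertices = _inner_simplex_vertices(x, m)
    a = np.linalg.inv(x[vertices])
    chi = np.clip(x @ a, 0.0, 1.0)
    chi /= chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    weights = np.array([model.stationary[crisp == i].sum() for i in range(m)])
    dg = macrostate_free_energy(weights)
    return MacrostatePartition(memberships=chi, crisp=crisp, n_macrostates=m,
                               weights=weights, free_energies=dg,
                               temperature=298.0)


def macrostate_free_energy(weights, temperature: float = 298.0,
                           kB: float = KB_KCAL) -> np.ndarray:
    """dG_I = -kB T ln(sum_{j in S_I} pi_j), shifted so the minimum is 0.

    Empty macrostates (zero weight) get +inf.  Pass ``kB=1, temperature=1``
    for unit mode.  The result is invariant under uniform rescaling of the
    weights.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("stationary weights must be non-negative")
    with np.errstate(divide="ignore"):
        g = -kB * temperature * np.log(w)
    finite = np.isfinite(g)
    if not finite.any():
        raise ValueError("all macrostates are empty")
    return g - g[finite].min()


def macrostate_weights(partition_crisp, pi, active_set=None, m=None) -> np.ndarray:
    """Aggregate microstate stationary weights into macrostate weights."""
    crisp = np.asarray(partition_crisp, dtype=int)
    pi = np.asarray(pi, dtype=float)
    if m is None:
        m = crisp.max() + 1
    out = np.zeros(m)
    np.add.at(out, crisp, pi)
    return out
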