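"""Transition path theory on Markov state models.

Given a reversible MSM and disjoint source/sink sets A and B, computes the
forward/backward committors, gross and net reactive fluxes

    f_ij = pi_i q-_i T_ij q+_j      (gross, i != j)
    f+_ij = max(0, f_ij - f_ji)     (net)

the total A->B flux, the transition rate, a deterministic bottleneck
(widest-path) pathway decomposition with flux fractions, and macrostate
coarse-graining of the flux network.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .msm import MarkovModel


@dataclass
class FluxNetwork:
    source: np.ndarray
    sink: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    gross: np.ndarray
    net: np.ndarray
    total_flux: float
    rate: float                 # per lag time
    stationary: np.ndarray
    pathways: list = field(default_factory=list)   # [(state tuple, fraction)]

    def to_json(self, path):
        payload = {
            "source": self.source.tolist(), "sink": self.sink.tolist(),
            "q_plus": self.q_plus.tolist(), "q_minus": self.q_minus.tolist(),
            "gross": self.gross.tolist(), "net": self.net.tolist(),
            "total_flux": self.total_flux, "rate": self.rate,
            "stationary": self.stationary.tolist(),
            "pathways": [{"states": list(map(int, p)), "fraction": f}
                         for p, f in self.pathways],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def committor(model: MarkovModel, source, sink):
    """Forward and backward committors of the A -> B transition.

    q+ solves sum_j T_ij q+_j = q+_i on intermediate states with q+ = 0 on A
    and 1 on B (linear solve); q- solves the analogous problem under the
    time-reversed chain (for reversible models q- = 1 - q+).
    """
    a = np.asarray(source, dtype=int)
    b = np.asarray(sink, dtype=int)
    n = model.n_states
    if a.size == 0 or b.size == 0:
        raise ValueError("source and sink must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("source and sink must be disjoint")
    t = model.transition_matrix
    pi = model.stationary

    def solve(tmat, one_set, zero_set):
        q = np.zeros(n)
        q[one_set] = 1.0
        inter = np.setdiff1d(np.arange(n), np.concatenate([one_set, zero_set]))
        if inter.size:
            m = np.eye(inter.size) - tmat[np.ix_(inter, inter)]
            rhs = tmat[np.ix_(inter, one_set)].sum(axis=1)
            q[inter] = np.linalg.solve(m, rhs)
        return q

    q_plus = solve(t, b, a)
    t_rev = (pi[None, :] * t.T) / pi[:, None]   # time-reversed chain
    q_minus = solve(t_rev, a, b)
    return q_plus, q_minus


def flux(model: MarkovModel, source, sink, q_plus=None, q_minus=None) -> FluxNetwork:
    """Reactive flux network between source and sink sets."""
    a = np.asarray(source, dtype=int)
    b = np.asarray(sink, dtype=int)
    if q_plus is None or q_minus is None:
        q_plus, q_minus = committor(model, a, b)
    pi = model.stationary
    t = model.transition_matrix
    gross = pi[:, None] * q_minus[:, None] * t * q_plus[None, :]
    np.fill_diagonal(gross, 0.0)
    net = np.maximum(0.0, gross - gross.T)
    not_a = np.setdiff1d(np.arange(model.n_states), a)
    total = float(net[np.ix_(a, not_a)].sum())
    denom = float(pi @ q_minus)
    rate = total / denom if denom > 0 else np.nan
    return FluxNetwork(source=a, sink=b, q_plus=q_plus, q_minus=q_minus,
                       gross=gross, net=net, total_flux=total, rate=rate,
                       stationary=pi)


def _widest_path(net: np.ndarray, source, sink):
    """Highest-bottleneck A->B path; ties: fewer edges, then lexicographic.

    Returns (path tuple, bottleneck capacity) or (None, 0.0).
    """
    n = net.shape[0]
    sink_set = set(int(s) for s in sink)
    # heap entries: (-bottleneck, n_edges, path)
    heap = [(-np.inf, 0, (int(s),)) for s in sorted(int(s) for s in source)]
    heapq.heapify(heap)
    best = {}
    while heap:
        neg_cap, n_edges, path = heapq.heappop(heap)
        cap = -neg_cap
        node = path[-1]
        if node in sink_set:
            return path, cap
        key = best.get(node)
        if key is not None and key < (neg_cap, n_edges, path):
            continue
        for nxt in range(n):
            w = net[node, nxt]
            if w <= 0 or nxt in path:
                continue
            new_cap = min(cap, w)
            entry = (-new_cap, n_edges + 1, path + (nxt,))
            prev = best.get(nxt)
            cand_key = (-new_cap, n_edges + 1, path + (nxt,))
            if prev is None or cand_key < prev:
                best[nxt] = cand_key
                heapq.heappush(heap, entry)
    return None, 0.0


def decompose_pathways(fluxnet: FluxNetwork, max_paths: int = None,
                       fraction: float = None, tol: float = 1e-12) -> list:
    """Iterative bottleneck decomposition of the net flux into pathways.

    Repeatedly extracts the A->B path with the largest minimum edge flux
    (ties broken by fewer edges, then lexicographic state order), subtracts
    its capacity from its edges, and records fraction = capacity / F.  Stops
    at ``max_paths`` paths, at cumulative ``fraction``, or when the network
    disconnects.  The pathway list is also stored on the network.
    """
    if max_paths is None and fraction is None:
        fraction = 1.0 - 1e-9
    net = fluxnet.net.copy()
    total = fluxnet.total_flux
    paths = []
    if total <= 0:
        fluxnet.pathways = paths
        return paths
    cumulative = 0.0
    while True:
        if max_paths is not None and len(paths) >= max_paths:
            break
        if fraction is not None and cumulative >= fraction:
            break
        path, cap = _widest_path(net, fluxnet.source, fluxnet.sink)
        if path is None or cap <= tol * total:
            break
        for u, v in zip(path[:-1], path[1:]):
            net[u, v] -= cap
        paths.append((path, cap / total))
        cumulative += cap / total
    fluxnet.pathways = paths
    return paths


def coarse_grain_flux(fluxnet: FluxNetwork, crisp, n_macrostates: int = None,
                      ns_per_lag: float = None):
    """Aggregate the net flux over a crisp macrostate partition.

    Returns a dict with the macro net-flux matrix (sum of micro net fluxes
    across partition blocks, intra-block flux zeroed), per-pair rates
    flux / stationary weight of the origin block (per lag time, and per ns
    when ``ns_per_lag`` is given), and the conserved total A->B flux.
    """
    crisp = np.asarray(crisp, dtype=int)
    if crisp.shape[0] != fluxnet.net.shape[0]:
        raise ValueError("partition must cover every state of the flux network")
    m = int(crisp.max()) + 1 if n_macrostates is None else int(n_macrostates)
    macro = np.zeros((m, m))
    for i_block in range(m):
        sel_i = crisp == i_block
        for j_block in range(m):
            if i_block == j_block:
                continue
            macro[i_block, j_block] = fluxnet.net[np.ix_(sel_i, crisp == j_block)].sum()
    weights = np.array([fluxnet.stationary[crisp == i].sum() for i in range(m)])
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(weights[:, None] > 0, macro / weights[:, None], np.nan)
    out = {"flux": macro, "rates_per_lag": rates, "weights": weights,
           "total_flux": fluxnet.total_flux}
    if ns_per_lag is not None:
        out["rates_per_ns"] = rates / ns_per_lag
    return out


def macro_flux_network(fluxnet: FluxNetwork, crisp, source_macro: int,
                       sink_macro: int, n_macrostates: int = None) -> FluxNetwork:
    """Project the reactive flux onto macrostates for pathway analysis.

    Block-to-block gross fluxes are summed and netted (f+_IJ = max(0,
    F_IJ - F_JI)); committors become stationary-weighted block averages.
    Pathway decomposition on the returned network yields the
    macrostate-level transition paths and their flux fractions.
    """
    cg = coarse_grain_flux(fluxnet, crisp, n_macrostates)
    macro = cg["flux"]
    net = np.maximum(0.0, macro - macro.T)
    w = cg["weights"]
    m = len(w)
    qp = np.zeros(m)
    qm = np.zeros(m)
    for i_block in range(m):
        selb = crisp == i_block
        if w[i_block] > 0:
            qp[i_block] = fluxnet.stationary[selb] @ fluxnet.q_plus[selb] / w[i_block]
            qm[i_block] = fluxnet.stationary[selb] @ fluxnet.q_minus[selb] / w[i_block]
    a = np.array([source_macro])
    b = np.array([sink_macro])
    total = float(net[source_macro, np.arange(m) != source_macro].sum())
    return FluxNetwork(source=a, sink=b, q_plus=qp, q_minus=qm,
                       gross=macro, net=net, total_flux=total,
                       rate=fluxnet.rate, stationary=w)


def cut_flux(fluxnet: FluxNetwork, left_set) -> float:
    """Total net flux across an arbitrary cut separating A-side from B-side.

    For any state set containing A and excluding B this equals the total
    flux (flux conservation).
    """
    left = np.asarray(left_set, dtype=int)
    right = np.setdiff1d(np.arange(fluxnet.net.shape[0]), left)
    return float(fluxnet.net[np.ix_(left, right)].sum()
                 - fluxnet.net[np.ix_(right, left)].sum())
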