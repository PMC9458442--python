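"""Synthetic data generators with recorded ground truth.

Desk-scale stand-ins for the microsecond MD trajectories the kinetic
pipeline is designed for:

* discrete Markov chains sampled from a known transition matrix
  (ground truth for MSM estimator recovery),
* overdamped Langevin dynamics on analytic potentials with known minima and
  barrier heights (ground truth for TICA / clustering / PCCA+ recovery and
  for PMF estimation),
* an idealized three-or-more base-pair DNA duplex parameterized by a flip
  angle (geometry fixture for the collective-variable operations).

Every generator is deterministic given its spec's seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .featurize import FeatureSeries
from .trajectory import Trajectory

SEED_MODULUS = 2**31


def derive_seed(seed: int, offset: int) -> int:
    """Derive a per-component seed from one global seed by a fixed offset."""
    return (int(seed) * 1000003 + int(offset)) % SEED_MODULUS


# ---------------------------------------------------------------------------
# Analytic potentials
# ---------------------------------------------------------------------------

class HarmonicPotential:
    """V(x) = 1/2 k (x - x0)^2, one-dimensional."""

    ndim = 1

    def __init__(self, k: float = 1.0, x0: float = 0.0):
        self.k = float(k)
        self.x0 = float(x0)
        self.minima = np.array([[x0]])
        self.barrier_height = 0.0
        self.bounding_box = 50.0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return 0.5 * self.k * np.sum((x - self.x0) ** 2, axis=-1)

    def gradient(self, x):
        return self.k * (np.asarray(x, dtype=float) - self.x0)


class DoubleWellPotential:
    """V(x) = h ((x/a)^2 - 1)^2: minima at +-a, barrier h at x = 0."""

    ndim = 1

    def __init__(self, barrier: float = 3.0, a: float = 1.0):
        self.h = float(barrier)
        self.a = float(a)
        self.minima = np.array([[-a], [a]])
        self.barrier_height = self.h
        self.bounding_box = 20.0 * a

    def energy(self, x):
        s = np.sum(np.atleast_1d(np.asarray(x, dtype=float)) ** 2, axis=-1)
        return self.h * (s / self.a**2 - 1.0) ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return 4.0 * self.h * x / self.a**2 * (np.sum(x**2, axis=-1, keepdims=True) / self.a**2 - 1.0)


class FiveBasin2DPotential:
    """Sum of five inverted 2-D Gaussians plus a quartic confining bowl.

    Emulates a free-energy landscape with five metastable basins; the deepest
    basin (index 0, "state 1") is the global minimum.  Depths, centers and
    widths are configurable; defaults give inter-basin barriers of a few kT
    at kT ~ 0.6 kcal/mol so an overdamped walker recrosses every basin many
    times within ~1e6 steps while remaining clearly metastable.
    """

    ndim = 2

    DEFAULT_CENTERS = np.array([
        [0.0, 0.0],    # state 1 - deepest, "closed" basin
        [0.2, 2.0],    # state 2
        [2.0, -0.8],   # state 3
        [2.1, 1.6],    # state 4
        [3.6, 0.4],    # state 5 - "flipped-out" basin
    ])
    DEFAULT_DEPTHS = np.array([4.6, 3.9, 4.2, 3.8, 3.6])  # kcal/mol
    DEFAULT_SIGMA = 0.72

    def __init__(self, centers=None, depths=None, sigmas=None, confine=0.02):
        self.centers = np.array(self.DEFAULT_CENTERS if centers is None else centers, dtype=float)
        self.depths = np.array(self.DEFAULT_DEPTHS if depths is None else depths, dtype=float)
        if sigmas is None:
            sigmas = np.full(len(self.centers), self.DEFAULT_SIGMA)
        self.sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (len(self.centers),)).copy()
        if self.centers.shape != (len(self.depths), 2):
            raise ValueError("centers must be (n_basins, 2) matching depths")
        if np.any(self.depths <= 0) or np.any(self.sigmas <= 0):
            raise ValueError("basin depths and widths must be positive")
        self.confine = float(confine)
        self.center_of_mass = self.centers.mean(axis=0)
        self.minima = self.centers  # approximate; exact minima shift slightly
        self.bounding_box = 25.0

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        d2 = np.sum((x[..., None, :] - self.centers) ** 2, axis=-1)
        wells = -np.sum(self.depths * np.exp(-0.5 * d2 / self.sigmas**2), axis=-1)
        r = x - self.center_of_mass
        return wells + self.confine * np.sum(r**4, axis=-1)

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        diff = x[..., None, :] - self.centers            # (..., 5, 2)
        d2 = np.sum(diff**2, axis=-1)                    # (..., 5)
        w = self.depths / self.sigmas**2 * np.exp(-0.5 * d2 / self.sigmas**2)
        grad = np.sum(w[..., None] * diff, axis=-2)
        r = x - self.center_of_mass
        return grad + 4.0 * self.confine * r**3

    def basin_labels(self, x):
        """Ground-truth label: nearest basin center in Euclidean distance."""
        x = np.asarray(x, dtype=float)
        d2 = np.sum((x[..., None, :] - self.centers) ** 2, axis=-1)
        return np.argmin(d2, axis=-1)


POTENTIALS = {
    "harmonic": HarmonicPotential,
    "double-well": DoubleWellPotential,
    "five-basin-2d": FiveBasin2DPotential,
}


def make_potential(potential_id: str, **kwargs):
    try:
        return POTENTIALS[potential_id](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown potential_id {potential_id!r}; valid ids: {sorted(POTENTIALS)}"
        ) from None


# ---------------------------------------------------------------------------
# Discrete Markov chains
# ---------------------------------------------------------------------------

@dataclass
class MarkovChainSpec:
    """A known row-stochastic transition matrix to sample trajectories from."""

    transition_matrix: np.ndarray
    n_steps: int
    n_trajectories: int = 1
    seed: int = 0
    start_state: int = 0

    def __post_init__(self):
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0) or np.any(T > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = T.sum(axis=1)
        bad = np.flatnonzero(np.abs(rowsums - 1.0) > 1e-12)
        if bad.size:
            raise ValueError(
                f"row {bad[0]} of the transition matrix sums to {rowsums[bad[0]]!r}, not 1"
            )
        self.transition_matrix = T
        if self.n_steps < 1 or self.n_trajectories < 1:
            raise ValueError("n_steps and n_trajectories must be positive")
        if not 0 <= self.start_state < T.shape[0]:
            raise ValueError("start_state out of range")


def sample_markov_chain(spec: MarkovChainSpec) -> list:
    """Sample integer state sequences from a known transition matrix.

    Returns ``n_trajectories`` arrays of length ``n_steps`` each (the first
    entry is the start state).  Deterministic given the spec seed.
    """
    T = spec.transition_matrix
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    cum_rows = [row.tolist() for row in cum]
    out = []
    for traj_idx in range(spec.n_trajectories):
        rng = np.random.default_rng(derive_seed(spec.seed, traj_idx))
        u = rng.random(spec.n_steps - 1)
        states = np.empty(spec.n_steps, dtype=np.int64)
        s = spec.start_state
        states[0] = s
        for t in range(spec.n_steps - 1):
            s = bisect.bisect_right(cum_rows[s], u[t])
            states[t + 1] = s
        out.append(states)
    return out


# ---------------------------------------------------------------------------
# Overdamped Langevin dynamics
# ---------------------------------------------------------------------------

@dataclass
class LangevinSpec:
    """Overdamped (Brownian) dynamics on an analytic potential.

    Update rule: ``x <- x - (dt/gamma) grad V(x) + sqrt(2 kT dt/gamma) xi``
    with standard-normal ``xi``.  Optional orthogonal fast-noise dimensions
    (independent OU processes with a stiff harmonic restoring force) emulate
    the fast degrees of freedom TICA is expected to discard.
    """

    potential_id: str = "double-well"
    kT: float = 0.596           # kcal/mol, ~298 K
    friction: float = 1.0      # gamma, inverse-time units
    dt: float = 0.01
    n_steps: int = 100000
    seed: int = 0
    x0: np.ndarray = None
    n_noise_dims: int = 0
    noise_stiffness: float = 25.0
    potential_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0 or self.friction <= 0 or self.kT < 0:
            raise ValueError("dt and friction must be positive, kT non-negative")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")


def simulate_langevin(spec: LangevinSpec):
    """Integrate overdamped Langevin dynamics.

    Returns
    -------
    fs : FeatureSeries
        Positions per frame; fast-noise dimensions (if any) appended as
        extra columns labelled ``noise*``.
    labels : ndarray of int
        Ground-truth index of the nearest potential basin per frame.
    """
    pot = make_potential(spec.potential_id, **spec.potential_kwargs)
    ndim = pot.ndim
    rng = np.random.default_rng(derive_seed(spec.seed, 17))
    x = np.array(pot.minima[0], dtype=float) if spec.x0 is None \
        else np.atleast_1d(np.asarray(spec.x0, dtype=float))
    if x.shape != (ndim,):
        raise ValueError(f"x0 must have dimension {ndim}")

    mob = spec.dt / spec.friction
    amp = np.sqrt(2.0 * spec.kT * spec.dt / spec.friction)
    n = spec.n_steps
    xs = np.empty((n, ndim))
    noise = rng.standard_normal((n - 1, ndim)) if spec.kT > 0 else np.zeros((n - 1, ndim))
    box = pot.bounding_box
    xs[0] = x
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(1, n):
            x = x - mob * pot.gradient(x) + amp * noise[t - 1]
            xs[t] = x
    if not np.all(np.isfinite(xs)) or np.max(np.abs(xs)) > box:
        raise RuntimeError(
            f"trajectory left the bounding box (|x| > {box}); "
            "the time step dt is likely unstable for this potential"
        )

    cols = [xs]
    lab = [f"x{j}" for j in range(ndim)]
    if spec.n_noise_dims > 0:
        # stiff OU dimensions: relaxation ~ gamma/k_fast, much faster than wells
        z = np.zeros(spec.n_noise_dims)
        zn = rng.standard_normal((n - 1, spec.n_noise_dims))
        zs = np.empty((n, spec.n_noise_dims))
        zs[0] = z
        decay = 1.0 - mob * spec.noise_stiffness
        if not -1.0 < decay < 1.0:
            raise ValueError("noise_stiffness unstable at this dt/friction")
        for t in range(1, n):
            z = decay * z + amp * zn[t - 1]
            zs[t] = z
        cols.append(zs)
        lab += [f"noise{j}" for j in range(spec.n_noise_dims)]

    fs = FeatureSeries(values=np.hstack(cols), dt=spec.dt, labels=lab)
    if hasattr(pot, "basin_labels"):
        labels = pot.basin_labels(xs)
    else:
        d2 = np.sum((xs[:, None, :] - pot.minima) ** 2, axis=-1)
        labels = np.argmin(d2, axis=-1)
    return fs, labels


# ---------------------------------------------------------------------------
# Toy DNA duplex
# ---------------------------------------------------------------------------

@dataclass
class ToyDuplexSpec:
    """Idealized duplex for collective-variable testing.

    One flipping ("lesion") pyrimidine on the middle base pair of strand A,
    rotated by ``flip_angle`` about the axis through its two flanking
    phosphate groups: 0 deg is stacked in-helix facing its partner, 180 deg
    fully extrahelical on the major-groove side.  Planar six-membered rings
    and one P atom per residue only — a geometry fixture, not a physical
    B-DNA model.
    """

    n_base_pairs: int = 3
    flip_angle: float = 0.0
    rise: float = 3.4       # Angstrom
    twist: float = 36.0     # degrees
    seed: int = 0
    jitter: float = 0.0     # optional seeded coordinate jitter, Angstrom

    def __post_init__(self):
        if self.n_base_pairs < 3:
            raise ValueError(
                "n_base_pairs must be >= 3: the flip pseudodihedral needs "
                "flanking base pairs on both sides of the lesion"
            )
        if not 0.0 <= self.flip_angle < 360.0:
            raise ValueError("flip_angle must lie in [0, 360)")


_RING_NAMES = ["N1", "C2", "N3", "C4", "C5", "C6"]
_RING_ELEMENTS = ["N", "C", "N", "C", "C", "C"]
_P_RADIUS = 9.0
_RING_CENTER_RADIUS = 2.6
_RING_RADIUS = 1.4


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def build_toy_duplex(spec: ToyDuplexSpec) -> Trajectory:
    """Construct the single-frame toy duplex with labeled lesion/partner.

    The lesion residue is named ``TG`` (chain A, middle base pair) and its
    partner ``DA`` on chain B at the same base-pair index.  Residue ids on
    chain A run 1..n; on chain B n+1..2n, antiparallel numbering so that the
    partner of chain-A residue i is chain-B residue 2n+1-i.
    """
    n = spec.n_base_pairs
    lesion_bp = n // 2  # 0-based index of the flipping base pair
    coords, names, resids, resnames, chains, elements = [], [], [], [], [], []

    def add_residue(bp_index, strand):
        """strand 0 = chain A, strand 1 = chain B (antiparallel)."""
        theta = np.deg2rad(spec.twist * bp_index)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        sgn = 1.0 if strand == 0 else -1.0
        z = np.array([0.0, 0.0, spec.rise * bp_index])
        e2 = np.cross([0.0, 0.0, 1.0], u)
        p_pos = sgn * _P_RADIUS * u + z
        ring_center = sgn * _RING_CENTER_RADIUS * u + z
        ring = [ring_center - sgn * _RING_RADIUS *
                (np.cos(np.deg2rad(60 * k)) * u - np.sin(np.deg2rad(60 * k)) * e2)
                for k in range(6)]
        if strand == 0:
            resid, chain = bp_index + 1, "A"
            resname = "TG" if bp_index == lesion_bp else "DT"
        else:
            resid, chain = 2 * n - bp_index, "B"
            resname = "DA"
        for name, el, pos in zip(["P"] + _RING_NAMES, ["P"] + _RING_ELEMENTS,
                                 [p_pos] + ring):
            coords.append(pos)
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            elements.append(el)

    for bp in range(n):
        add_residue(bp, 0)
    for bp in range(n):
        add_residue(bp, 1)

    coords = np.array(coords)
    resids = np.array(resids)
    chains = np.array(chains)
    names = np.array(names)

    # flip: rigid rotation of the lesion ring about the axis through the
    # flanking phosphates of the lesion strand (5' and 3' neighbours)
    if spec.flip_angle != 0.0:
        p_prev = coords[(resids == lesion_bp) & (chains == "A") & (names == "P")][0]
        p_next = coords[(resids == lesion_bp + 2) & (chains == "A") & (names == "P")][0]
        R = _rotation_about_axis(p_next - p_prev, spec.flip_angle)
        ring_mask = (resids == lesion_bp + 1) & (chains == "A") & (names != "P")
        coords[ring_mask] = (coords[ring_mask] - p_prev) @ R.T + p_prev

    if spec.jitter > 0:
        rng = np.random.default_rng(derive_seed(spec.seed, 23))
        coords = coords + spec.jitter * rng.standard_normal(coords.shape)

    traj = Trajectory(
        coords=coords[None], atom_names=names, res_ids=resids,
        res_names=np.array(resnames), chain_ids=chains,
        elements=np.array(elements),
    )
    d = np.linalg.norm(traj.coords[0][:, None] - traj.coords[0][None], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 0.5:
        raise ValueError("degenerate geometry: interatomic distance <= 0.5 A")
    return traj


def lesion_partner_residues(spec: ToyDuplexSpec):
    """(lesion_resid chain A, partner_resid chain B) for a duplex spec."""
    lesion = spec.n_base_pairs // 2 + 1
    partner = 2 * spec.n_base_pairs - (lesion - 1)
    return lesion, partner


def build_flip_trajectory(spec: ToyDuplexSpec, angles) -> Trajectory:
    """Multi-frame duplex sweeping the flip angle (one MODEL per angle)."""
    from dataclasses import replace
    frames = [build_toy_duplex(replace(spec, flip_angle=float(a))) for a in angles]
    base = frames[0]
    return Trajectory(
        coords=np.concatenate([f.coords for f in frames], axis=0),
        atom_names=base.atom_names, res_ids=base.res_ids,
        res_names=base.res_names, chain_ids=base.chain_ids,
        elements=base.elements, masses=base.masses,
    )
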