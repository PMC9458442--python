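"""Extended-system adaptive-biasing-force metadynamics (meta-eABF), 1-D.

A fictitious variable lambda is coupled to the collective variable xi(x) by
a stiff harmonic spring (1/2 k_u (xi - lambda)^2) and evolved by overdamped
Langevin dynamics alongside the physical coordinate.  Two biases act on
lambda simultaneously:

* ABF: the running per-bin average of the instantaneous spring force is
  subtracted (ramped in after ``n_full`` samples per bin), so lambda feels a
  nearly flat landscape once the mean force estimate converges;
* metadynamics: repulsive Gaussians deposited on lambda at a fixed stride
  push the system out of visited regions early on.

Because the metadynamics Gaussians perturb the lambda marginal, the PMF is
recovered with the CZAR estimator, which only needs the *physical* CV
histogram and the conditional mean of lambda:

    dA/dxi = -kT d ln rho(xi)/dxi + k_u ( <lambda|xi> - xi )

integrated by the trapezoid rule and shifted so the minimum is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import derive_seed


@dataclass
class MetaEABFParams:
    """Grid and bias hyperparameters (Colvars-style conventions).

    Defaults: bin width 5 degrees for periodic/angle CVs or 0.1 for
    distance-like CVs (set explicitly), ramp-in after 200 samples per bin,
    Gaussians of 0.1 kcal/mol height and two-bin width every 1000 steps.
    """

    grid_min: float
    grid_max: float
    bin_width: float = 0.1
    n_full: int = 200
    gaussian_height: float = 0.1     # kcal/mol
    gaussian_width: float = None     # CV units; default 2 bins
    deposit_stride: int = 1000
    abf_enabled: bool = True

    def __post_init__(self):
        if self.grid_max <= self.grid_min:
            raise ValueError("empty CV grid")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.gaussian_width is None:
            self.gaussian_width = 2.0 * self.bin_width
        if self.gaussian_height < 0:
            raise ValueError("Gaussian height must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round((self.grid_max - self.grid_min) / self.bin_width))

    def centers(self) -> np.ndarray:
        return self.grid_min + (np.arange(self.n_bins) + 0.5) * self.bin_width


@dataclass
class ExtendedSystem:
    """Physical 1-D system plus the harmonically coupled extended variable.

    ``cv_mode`` is "identity" (xi = x) or "periodic" (xi = x wrapped to the
    grid period, for angles).  ``k_u`` defaults to kT / bin_width^2 so the
    coupling fluctuation is about one bin width.
    """

    potential: object
    kT: float = 0.596
    friction: float = 1.0
    dt: float = 0.001
    cv_mode: str = "identity"
    k_u: float = None
    ext_kT: float = None
    ext_friction: float = None

    def __post_init__(self):
        if getattr(self.potential, "ndim", 1) != 1:
            raise ValueError("the meta-eABF engine is one-dimensional")
        if self.cv_mode not in ("identity", "periodic"):
            raise ValueError("cv_mode must be 'identity' or 'periodic'")
        if self.ext_kT is None:
            self.ext_kT = self.kT
        if self.ext_friction is None:
            self.ext_friction = self.friction


@dataclass
class BiasState:
    """ABF accumulators, deposited Gaussians, and CZAR histograms."""

    params: MetaEABFParams
    k_u: float
    abf_force_sum: np.ndarray = None    # per-bin sum of spring force on lambda
    abf_count: np.ndarray = None
    gaussians: list = field(default_factory=list)   # (center, height, width)
    metad_force: np.ndarray = None      # tabulated -dVg/dlambda per bin center
    xi_count: np.ndarray = None         # physical CV histogram (CZAR)
    lambda_sum: np.ndarray = None       # sum of lambda per xi bin (CZAR)
    n_reflections: int = 0

    def __post_init__(self):
        n = self.params.n_bins
        for name in ("abf_force_sum", "abf_count", "metad_force",
                     "xi_count", "lambda_sum"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n))

    def mean_force(self) -> np.ndarray:
        """Per-bin running mean of the spring force on lambda."""
        with np.errstate(invalid="ignore"):
            return np.where(self.abf_count > 0,
                            self.abf_force_sum / np.maximum(self.abf_count, 1), 0.0)


@dataclass
class PMFProfile:
    """Binned free-energy profile (kcal/mol), min-shifted to zero."""

    centers: np.ndarray
    values: np.ndarray
    errors: np.ndarray = None
    periodic: bool = False

    def __post_init__(self):
        if self.errors is None:
            self.errors = np.zeros_like(self.values)

    @property
    def range(self) -> float:
        return float(np.nanmax(self.values) - np.nanmin(self.values))


def _scalar_gradient(potential):
    """Fast scalar dV/dx closure for the 1-D analytic potentials."""
    name = type(potential).__name__
    if name == "HarmonicPotential":
        k, x0 = potential.k, potential.x0
        return lambda x: k * (x - x0)
    if name == "DoubleWellPotential":
        h, a2 = potential.h, potential.a**2
        return lambda x: 4.0 * h * x / a2 * (x * x / a2 - 1.0)
    return lambda x: float(np.asarray(potential.gradient(np.array([x]))).ravel()[0])


def run_meta_eabf(system: ExtendedSystem, params: MetaEABFParams,
                  n_steps: int, seed: int = 0, x0: float = None):
    """Integrate the coupled (x, lambda) dynamics and collect bias statistics.

    Returns ``(xi_series, lambda_series, bias_state)``.  The run is
    deterministic given the seed.  lambda is reflected at the grid edges
    (count logged); for periodic CVs both variables wrap instead.
    """
    p = params
    period = p.grid_max - p.grid_min
    periodic = system.cv_mode == "periodic"
    k_u = system.k_u if system.k_u is not None else system.kT / p.bin_width**2
    gradv = _scalar_gradient(system.potential)

    # stability of the stiff coupling under explicit overdamped stepping
    if system.dt * k_u / min(system.friction, system.ext_friction) > 0.5:
        raise ValueError(
            "unstable time step: dt * k_u / friction must stay well below 1"
        )

    rng = np.random.default_rng(derive_seed(seed, 97))
    nb = p.n_bins
    centers = p.centers()
    state = BiasState(params=p, k_u=k_u)
    mob_x = system.dt / system.friction
    mob_l = system.dt / system.ext_friction
    amp_x = np.sqrt(2.0 * system.kT * system.dt / system.friction)
    amp_l = np.sqrt(2.0 * system.ext_kT * system.dt / system.ext_friction)

    x = float(system.potential.minima[0][0]) if x0 is None else float(x0)
    lam = min(max(x, p.grid_min + 0.5 * p.bin_width), p.grid_max - 0.5 * p.bin_width)
    noise = rng.standard_normal((n_steps, 2))
    xi_series = np.empty(n_steps)
    lam_series = np.empty(n_steps)

    abf_sum = state.abf_force_sum
    abf_cnt = state.abf_count
    metad_f = state.metad_force
    xi_cnt = state.xi_count
    lam_sum = state.lambda_sum
    gmin, bw, h, gw, stride = p.grid_min, p.bin_width, p.gaussian_height, \
        p.gaussian_width, p.deposit_stride
    n_full = p.n_full
    abf_on = p.abf_enabled

    def wrap(v):
        return (v - gmin) % period + gmin

    for t in range(n_steps):
        xi = wrap(x) if periodic else x
        delta = xi - lam
        if periodic:
            delta = (delta + 0.5 * period) % period - 0.5 * period
        spring = k_u * delta          # force on lambda; -spring acts on x

        b = int((lam - gmin) / bw)
        if b < 0:
            b = 0
        elif b >= nb:
            b = nb - 1
        abf_sum[b] += spring
        abf_cnt[b] += 1.0

        f_lam = spring
        if abf_on:
            cnt = abf_cnt[b]
            ramp = cnt / n_full if cnt < n_full else 1.0
            f_lam -= ramp * abf_sum[b] / cnt
        f_lam += metad_f[b]

        if h > 0.0 and (t + 1) % stride == 0:
            # tabulate force = -dVg/dlambda, pushing away from the deposit
            state.gaussians.append((lam, h, gw))
            d = centers - lam
            if periodic:
                d = (d + 0.5 * period) % period - 0.5 * period
            metad_f += h * d / gw**2 * np.exp(-0.5 * (d / gw) ** 2)

        # CZAR statistics use the physical CV
        bx = int((xi - gmin) / bw)
        if 0 <= bx < nb:
            xi_cnt[bx] += 1.0
            lam_val = lam
            if periodic:
                # accumulate lambda relative to the bin center to keep the
                # conditional mean well defined across the wrap
                lam_val = centers[bx] + ((lam - centers[bx] + 0.5 * period)
                                         % period - 0.5 * period)
            lam_sum[bx] += lam_val

        # coupling acts on x with the opposite sign of the spring force on lambda
        x = x - mob_x * (gradv(x) + spring) + amp_x * noise[t, 0]
        lam = lam + mob_l * f_lam + amp_l * noise[t, 1]
        if periodic:
            lam = wrap(lam)
        else:
            if lam < gmin:
                lam = 2.0 * gmin - lam
                state.n_reflections += 1
            elif lam > p.grid_max:
                lam = 2.0 * p.grid_max - lam
                state.n_reflections += 1
        xi_series[t] = wrap(x) if periodic else x
        lam_series[t] = lam

    return xi_series, lam_series, state


def _czar_gradient(xi_cnt, lam_sum, centers, bin_width, kT, k_u, periodic, period):
    """CZAR mean-force estimate per visited bin."""
    with np.errstate(divide="ignore", invalid="ignore"):
        logrho = np.log(xi_cnt)
        lam_mean = lam_sum / xi_cnt
    n = len(centers)
    dlog = np.full(n, np.nan)
    for i in range(n):
        im = (i - 1) % n if periodic else max(i - 1, 0)
        ip = (i + 1) % n if periodic else min(i + 1, n - 1)
        if xi_cnt[im] > 0 and xi_cnt[ip] > 0:
            span = (ip - im) % n if periodic else ip - im
            dlog[i] = (logrho[ip] - logrho[im]) / (span * bin_width)
    delta = lam_mean - centers
    if periodic:
        delta = (delta + 0.5 * period) % period - 0.5 * period
    return -kT * dlog + k_u * delta


def estimate_pmf(state: BiasState, xi_series, lam_series, kT: float,
                 periodic: bool = False, n_blocks: int = 5,
                 min_count: int = None, edge_trim: int = 2) -> PMFProfile:
    """CZAR estimate of the PMF from the biased run.

    Bins with fewer than ``min_count`` (default: the ABF ramp threshold)
    samples at either edge of the profile are trimmed; an *interior* gap
    raises instead of being interpolated.  On non-periodic grids the
    ``edge_trim`` outermost visited bins are additionally dropped: the
    reflecting wall on lambda distorts the biased marginal right at the
    boundary.  Per-bin standard errors come from block averaging over
    ``n_blocks`` contiguous time blocks.
    """
    p = state.params
    centers = p.centers()
    period = p.grid_max - p.grid_min
    if min_count is None:
        min_count = p.n_full
    visited = state.xi_count >= min_count
    if not visited.any():
        raise ValueError("no CV bin has enough samples to report a PMF")
    lo, hi = np.flatnonzero(visited)[[0, -1]]
    if not periodic:
        gap = np.flatnonzero(~visited[lo:hi + 1])
        if gap.size:
            raise ValueError(
                f"interior CV bins never visited (first gap at bin {lo + gap[0]}, "
                f"center {centers[lo + gap[0]]:.3g}); no silent interpolation"
            )
        lo, hi = lo + edge_trim, hi - edge_trim
        if hi <= lo:
            raise ValueError("profile empty after boundary trimming")
        sel = slice(lo, hi + 1)
    else:
        if (~visited).any():
            raise ValueError("periodic PMF requires every bin to be sampled")
        sel = slice(0, p.n_bins)

    def integrate(xi_cnt, lam_sum):
        grad = _czar_gradient(xi_cnt, lam_sum, centers, p.bin_width, kT,
                              state.k_u, periodic, period)
        g = grad[sel]
        a = np.zeros(len(g))
        for i in range(1, len(g)):
            a[i] = a[i - 1] + 0.5 * (g[i - 1] + g[i]) * p.bin_width
        return a - np.nanmin(a)

    values = integrate(state.xi_count, state.lambda_sum)

    # block-averaged error bars
    n = len(xi_series)
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    blocks = []
    for a, b in zip(edges[:-1], edges[1:]):
        cnt = np.zeros(p.n_bins)
        lsm = np.zeros(p.n_bins)
        idx = np.clip(((xi_series[a:b] - p.grid_min) / p.bin_width).astype(int),
                      0, p.n_bins - 1)
        np.add.at(cnt, idx, 1.0)
        np.add.at(lsm, idx, lam_series[a:b])
        if np.all(cnt[sel] > 1):
            blocks.append(integrate(cnt, lsm))
    if len(blocks) >= 2:
        errors = np.std(np.array(blocks), axis=0, ddof=1) / np.sqrt(len(blocks))
    else:
        errors = np.full(values.shape, np.nan)
    return PMFProfile(centers=centers[sel], values=values, errors=errors,
                      periodic=periodic)


def extract_barriers(profile: PMFProfile, reactant: float = None,
                     product: float = None, prominence: float = 0.2) -> dict:
    """Forward/reverse barrier heights between the two main PMF minima.

    Local minima are found by grid scan (a ``prominence`` filter in kcal/mol
    suppresses noise wiggles); the reactant defaults to the first minimum
    and the product to the last.  A monotone profile yields barrier 0
    ("barrier-free").  Explicit ``reactant``/``product`` CV positions
    override the automatic choice (nearest bin).
    """
    v = np.asarray(profile.values, dtype=float)
    c = np.asarray(profile.centers, dtype=float)
    n = len(v)
    minima = []
    for i in range(n):
        if profile.periodic:
            vm, vp = v[(i - 1) % n], v[(i + 1) % n]
        else:
            vm = v[i - 1] if i > 0 else np.inf
            vp = v[i + 1] if i < n - 1 else np.inf
        if v[i] <= vm and v[i] <= vp:
            minima.append(i)
    # prominence filter: a minimum must sit below its neighbourhood by margin
    strong = []
    for i in minima:
        left = v[:i][::-1] if not profile.periodic else np.roll(v, -i - 1)[::-1]
        right = v[i + 1:] if not profile.periodic else np.roll(v, -i - 1)
        rise_l = np.max(left) - v[i] if len(left) else np.inf
        rise_r = np.max(right) - v[i] if len(right) else np.inf
        if min(rise_l, rise_r) >= prominence or len(minima) == 1:
            strong.append(i)
    if not strong:
        strong = [int(np.argmin(v))]

    def nearest_bin(pos):
        return int(np.argmin(np.abs(c - pos)))

    if reactant is not None:
        i_r = nearest_bin(reactant)
    else:
        i_r = strong[0]
    if product is not None:
        i_p = nearest_bin(product)
    else:
        i_p = strong[-1]

    if i_r == i_p:
        return {"reactant": (float(c[i_r]), float(v[i_r])),
                "product": (float(c[i_p]), float(v[i_p])),
                "forward_barrier": 0.0, "reverse_barrier": 0.0,
                "barrier_position": None, "minima": [float(c[i]) for i in strong]}

    lo_i, hi_i = min(i_r, i_p), max(i_r, i_p)
    if profile.periodic and (i_r > i_p):
        seg = np.concatenate([v[i_r:], v[:i_p + 1]])
        off = i_r
    else:
        seg = v[lo_i:hi_i + 1]
        off = lo_i
    top = int(np.argmax(seg))
    vmax = float(seg[top])
    forward = max(0.0, vmax - float(v[i_r]))
    reverse = max(0.0, vmax - float(v[i_p]))
    pos = float(c[(off + top) % n])
    return {"reactant": (float(c[i_r]), float(v[i_r])),
            "product": (float(c[i_p]), float(v[i_p])),
            "forward_barrier": forward, "reverse_barrier": reverse,
            "barrier_position": pos, "minima": [float(c[i]) for i in strong]}
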