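"""Shared fixtures: expensive simulations are session-scoped so the
parameter-recovery, validation and acceptance tests reuse one realization."""

import numpy as np
import pytest

import flipmsm as fm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_duplex():
    return fm.build_toy_duplex(fm.ToyDuplexSpec(n_base_pairs=3))


@pytest.fixture(scope="session")
def five_state_chain():
    """A known 5-state reversible-ish transition matrix and a long sample."""
    t = np.array([
        [0.90, 0.04, 0.03, 0.02, 0.01],
        [0.05, 0.85, 0.05, 0.03, 0.02],
        [0.02, 0.03, 0.90, 0.03, 0.02],
        [0.01, 0.04, 0.05, 0.85, 0.05],
        [0.02, 0.02, 0.03, 0.03, 0.90],
    ])
    spec = fm.MarkovChainSpec(transition_matrix=t, n_steps=1_000_000, seed=2024)
    seqs = fm.sample_markov_chain(spec)
    return t, seqs[0]


@pytest.fixture(scope="session")
def five_basin_run():
    """1e6-step overdamped trajectory on the five-basin landscape plus the
    full analysis chain (TICA -> 300 microstates -> MSM -> PCCA+).  The MSM
    lag (100 frames) sits on the implied-timescale plateau."""
    spec = fm.LangevinSpec(potential_id="five-basin-2d", kT=0.596, dt=0.01,
                           n_steps=1_000_000, seed=7, n_noise_dims=4)
    fs, truth = fm.simulate_langevin(spec)
    model = fm.fit_tica(fs, lag=100)
    proj = fm.project(fs, model, variance_fraction=0.9)
    assign = fm.kmeans_cluster(proj, k=300, seed=0, max_fit_points=200_000)
    mm = fm.estimate_msm(assign.labels, 100, assign.segment_starts, n_states=300)
    part = fm.pcca_plus(mm, 5)
    return {"spec": spec, "features": fs, "truth": truth, "tica": model,
            "projected": proj, "assignment": assign, "msm": mm, "pcca": part}


@pytest.fixture(scope="session")
def double_well_pmf():
    """meta-eABF run on a symmetric double well with a 5.0 kcal/mol barrier."""
    kT = 0.596
    system = fm.ExtendedSystem(potential=fm.DoubleWellPotential(barrier=5.0),
                               kT=kT, dt=0.001)
    params = fm.MetaEABFParams(grid_min=-1.8, grid_max=1.8, bin_width=0.1)
    xi, lam, state = fm.run_meta_eabf(system, params, n_steps=2_000_000, seed=3)
    profile = fm.estimate_pmf(state, xi, lam, kT)
    return {"profile": profile, "state": state, "kT": kT}


@pytest.fixture(scope="session")
def flat_pmf():
    """meta-eABF run on a flat potential (zero-curvature harmonic)."""
    kT = 0.596
    system = fm.ExtendedSystem(potential=fm.HarmonicPotential(k=0.0),
                               kT=kT, dt=0.001)
    params = fm.MetaEABFParams(grid_min=-2.0, grid_max=2.0, bin_width=0.1)
    xi, lam, state = fm.run_meta_eabf(system, params, n_steps=1_000_000, seed=1)
    return fm.estimate_pmf(state, xi, lam, kT)


def macrostate_agreement(run) -> float:
    """Best-matching frame agreement between PCCA+ macrostates and the
    ground-truth basin labels (Hungarian matching over the confusion matrix)."""
    from scipy.optimize import linear_sum_assignment
    mm, part, assign, truth = run["msm"], run["pcca"], run["assignment"], run["truth"]
    pos = {s: i for i, s in enumerate(mm.active_set)}
    mask = np.isin(assign.labels, mm.active_set)
    macro = part.crisp[[pos[s] for s in assign.labels[mask]]]
    m = np.zeros((part.n_macrostates, 5))
    np.add.at(m, (macro, truth[mask]), 1.0)
    r, c = linear_sum_assignment(-m)
    return float(m[r, c].sum() / mask.sum())
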