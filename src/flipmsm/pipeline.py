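"""End-to-end orchestration of the kinetic analysis graph.

features -> TICA -> k-means microstates -> reversible MSM -> implied
timescales -> Chapman-Kolmogorov validation -> PCCA+ macrostates ->
stationary-weight free energies -> transition-path-theory flux and
pathways.  Every stage persists its artifact into the output directory and
the run is reproducible from the config and seeds alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from . import msm as fmsm
from . import tica as ftica
from . import tpt as ftpt
from .featurize import FeatureSeries, pairwise_distance_features

logger = logging.getLogger("flipmsm")


@dataclass
class RunConfig:
    """One document holding every knob of the analysis graph.

    Inputs are either precomputed feature tables (``feature_tables``) or
    PDB trajectories plus lesion/partner residue selections.  Lags are in
    frames; ``ns_per_frame`` optionally converts reported rates/timescales
    to physical units.
    """

    feature_tables: list = None
    trajectories: list = None
    lesion_resid: int = None
    partner_resid: int = None
    tica_lag: int = 10
    n_tica_dims: int = None
    kinetic_variance: float = 0.9
    n_microstates: int = 100
    msm_lag: int = 10
    n_macrostates: int = 5
    temperature: float = 298.0
    source_macrostate: int = 0
    sink_macrostate: int = None     # default: last macrostate
    ck_factors: tuple = (1, 2, 4)
    n_bootstrap: int = 100
    seed: int = 0
    ns_per_frame: float = None
    max_kmeans_fit_points: int = 200_000
    output_dir: str = "flipmsm_output"

    def validate(self):
        if (self.feature_tables is None) == (self.trajectories is None):
            raise ValueError("provide exactly one of feature_tables / trajectories")
        for group in (self.feature_tables, self.trajectories):
            for p in group or []:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.trajectories is not None and (
                self.lesion_resid is None or self.partner_resid is None):
            raise ValueError("PDB input needs lesion_resid and partner_resid")
        if self.msm_lag < 1 or self.tica_lag < 1:
            raise ValueError("lags must be positive frame counts")
        if self.n_macrostates < 1:
            raise ValueError("need at least one macrostate")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(**{k: v for k, v in fio.load_config(path).items()})


def load_features(config: RunConfig) -> FeatureSeries:
    """Stage 0: read features, or featurize PDB input (pair distances)."""
    if config.feature_tables is not None:
        parts = [fio.read_feature_table(p) for p in config.feature_tables]
        if len(parts) == 1:
            return parts[0]
        values = np.concatenate([p.values for p in parts])
        starts, off = [], 0
        for p in parts:
            starts.extend(b + off for b in p.segment_starts)
            off += p.n_frames
        return FeatureSeries(values=values, dt=parts[0].dt,
                             labels=parts[0].labels, segment_starts=starts)
    traj = fio.read_trajectory(config.trajectories)
    lesion = traj.select(res_id=config.lesion_resid, heavy_only=True)
    partner = traj.select(res_id=config.partner_resid, heavy_only=True)
    return pairwise_distance_features(traj, lesion, partner)


def run_pipeline(config: RunConfig, features: FeatureSeries = None) -> dict:
    """Execute the full analysis graph; returns the summary dictionary.

    ``features`` may be passed directly (library use); otherwise they are
    loaded per the config.  All intermediates are persisted under
    ``config.output_dir``.
    """
    config.validate() if features is None else None
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config": {k: v for k, v in vars(config).items()}, "warnings": []}

    stage = "features"
    try:
        fs = features if features is not None else load_features(config)
        fio.write_feature_table(fs, out / "features.tsv")

        stage = "tica"
        model = ftica.fit_tica(fs, lag=config.tica_lag)
        proj = ftica.project(fs, model, n_dims=config.n_tica_dims,
                             variance_fraction=(config.kinetic_variance
                                                if config.n_tica_dims is None else None))
        model.to_json(out / "tica.json")
        summary["tica"] = {
            "lag": config.tica_lag,
            "eigenvalues": model.eigenvalues[:10],
            "retained_dims": proj.n_features,
            "kinetic_variance": model.kinetic_variance_fractions()[proj.n_features - 1],
            "dropped_dims": model.n_dropped,
        }

        stage = "cluster"
        assign = fmsm.kmeans_cluster(proj, k=config.n_microstates, seed=config.seed,
                                     max_fit_points=config.max_kmeans_fit_points)
        fio.write_discrete(assign.labels, out / "microstates.tsv", assign.segment_starts)
        summary["cluster"] = {"k": assign.k, "inertia": assign.inertia}

        stage = "msm"
        mm = fmsm.estimate_msm(assign.labels, config.msm_lag, assign.segment_starts,
                               n_states=config.n_microstates)
        dropped_frames = int(np.sum(~np.isin(assign.labels, mm.active_set)))
        if dropped_frames:
            summary["warnings"].append(
                f"{dropped_frames} frames outside the largest connected set")
        fio.write_json({"lag": mm.lag, "active_set": mm.active_set,
                        "transition_matrix": mm.transition_matrix,
                        "stationary": mm.stationary,
                        "eigenvalues": mm.eigenvalues}, out / "msm.json")
        summary["msm"] = {"lag": mm.lag, "n_active": mm.n_states,
                          "top_eigenvalues": mm.eigenvalues[:6],
                          "timescales": mm.timescales(5)}

        stage = "implied_timescales"
        its_lags = sorted({max(1, config.msm_lag // 2), config.msm_lag,
                           2 * config.msm_lag})
        its = fmsm.implied_timescales(assign.labels, its_lags, assign.segment_starts,
                                      n_timescales=min(5, config.n_microstates - 1))
        fio.write_json(its, out / "implied_timescales.json")
        summary["implied_timescales"] = its

        if config.n_macrostates == 1:
            summary["macrostates"] = {"n": 1, "free_energies_kcal": [0.0],
                                      "weights": [1.0]}
            summary["ck_test"] = None
            summary["flux"] = None
            fio.write_json(summary, out / "summary.json")
            return summary

        stage = "pcca"
        part = fmsm.pcca_plus(mm, config.n_macrostates)
        dg = fmsm.macrostate_free_energy(part.weights, config.temperature)
        part.free_energies = dg
        part.temperature = config.temperature
        fio.write_json({"memberships": part.memberships, "crisp": part.crisp,
                        "weights": part.weights, "free_energies_kcal": dg},
                       out / "pcca.json")
        summary["macrostates"] = {"n": config.n_macrostates,
                                  "weights": part.weights,
                                  "free_energies_kcal": dg}

        stage = "chapman_kolmogorov"
        sets = [mm.active_set[part.crisp == i] for i in range(config.n_macrostates)]
        ck = fmsm.chapman_kolmogorov(assign.labels, config.msm_lag, sets,
                                     factors=config.ck_factors,
                                     segment_starts=assign.segment_starts,
                                     n_bootstrap=config.n_bootstrap,
                                     seed=config.seed)
        fio.write_json({"factors": ck.factors, "predicted": ck.predicted,
                        "estimated": ck.estimated, "lower": ck.band_lower,
                        "upper": ck.band_upper, "passed": ck.passed},
                       out / "cktest.json")
        summary["ck_test"] = {"passed": ck.passed, "factors": ck.factors,
                              "confidence": ck.confidence}

        stage = "tpt"
        src = config.source_macrostate
        snk = config.sink_macrostate if config.sink_macrostate is not None \
            else config.n_macrostates - 1
        a = np.flatnonzero(part.crisp == src)
        b = np.flatnonzero(part.crisp == snk)
        net = ftpt.flux(mm, a, b)
        macro_net = ftpt.macro_flux_network(net, part.crisp, src, snk,
                                            config.n_macrostates)
        paths = ftpt.decompose_pathways(macro_net, max_paths=10)
        macro = ftpt.coarse_grain_flux(
            net, part.crisp,
            ns_per_lag=(config.ns_per_frame * config.msm_lag
                        if config.ns_per_frame else None))
        net.to_json(out / "flux.json")
        fio.write_json(macro, out / "macro_flux.json")
        summary["flux"] = {
            "source": src, "sink": snk,
            "total_flux_per_lag": net.total_flux, "rate_per_lag": net.rate,
            "pathways": [{"macrostates": list(map(int, p)), "fraction": f}
                         for p, f in paths],
        }
        if config.ns_per_frame:
            summary["flux"]["rate_per_ns"] = net.rate / (config.ns_per_frame
                                                         * config.msm_lag)
    except Exception as exc:
        fio.write_json(summary, out / "summary.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    fio.write_json(summary, out / "summary.json")
    return summary
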