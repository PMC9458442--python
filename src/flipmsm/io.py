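"""Readers and writers for the pipeline's on-disk formats.

PDB (multi-MODEL, via biotite) for coordinate trajectories; tab-delimited
numeric text with a header row for feature tables, CV series, discrete
trajectories and PMF profiles; JSON for fitted models and summaries;
JSON/YAML for run configurations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from biotite.structure import AtomArray, stack
from biotite.structure.io.pdb import PDBFile

from .featurize import FeatureSeries
from .trajectory import Trajectory


# ---------------------------------------------------------------------------
# PDB trajectories
# ---------------------------------------------------------------------------

def _to_atom_array(traj: Trajectory, frame: int) -> AtomArray:
    arr = AtomArray(traj.n_atoms)
    arr.coord = traj.coords[frame].astype(np.float32)
    arr.chain_id = traj.chain_ids
    arr.res_id = traj.res_ids
    arr.res_name = traj.res_names
    arr.atom_name = traj.atom_names
    arr.element = traj.elements
    arr.hetero = np.zeros(traj.n_atoms, dtype=bool)
    return arr


def write_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a standard PDB file, one MODEL per frame."""
    models = stack([_to_atom_array(traj, i) for i in range(traj.n_frames)])
    pdb = PDBFile()
    pdb.set_structure(models)
    pdb.write(str(path))


def _read_single_pdb(path) -> Trajectory:
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=None)  # AtomArrayStack
    except Exception as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    return Trajectory(
        coords=np.asarray(arr.coord, dtype=float),
        atom_names=arr.atom_name,
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name,
        chain_ids=arr.chain_id,
        elements=np.char.upper(arr.element.astype("U2")),
    )


def read_trajectory(paths) -> Trajectory:
    """Read one or more multi-MODEL PDB files into a single trajectory.

    Each file becomes one independent segment; atom counts must agree
    across files and MODELs.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    trajs = []
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(p)
        trajs.append(_read_single_pdb(p))
    return Trajectory.concatenate(trajs)


# ---------------------------------------------------------------------------
# Delimited numeric tables
# ---------------------------------------------------------------------------

def write_feature_table(fs: FeatureSeries, path, extra_columns: dict = None) -> None:
    """Tab-delimited feature table; segment starts kept in a comment line."""
    df = pd.DataFrame(fs.values, columns=fs.labels)
    if extra_columns:
        for name, col in extra_columns.items():
            df[name] = col
    with open(path, "w") as fh:
        fh.write("# segment_starts: " + ",".join(map(str, fs.segment_starts))
                 + f"\t dt: {fs.dt}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_feature_table(path, feature_columns=None) -> FeatureSeries:
    starts, dt = [0], 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for chunk in first[1:].split("\t"):
                key, _, val = chunk.partition(":")
                if key.strip() == "segment_starts":
                    starts = [int(s) for s in val.split(",")]
                elif key.strip() == "dt":
                    dt = float(val)
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    if feature_columns is not None:
        df = df[list(feature_columns)]
    return FeatureSeries(values=df.to_numpy(dtype=float), dt=dt,
                         labels=list(df.columns), segment_starts=starts)


def write_discrete(labels, path, segment_starts=(0,)) -> None:
    with open(path, "w") as fh:
        fh.write("# segment_starts: " + ",".join(map(str, segment_starts)) + "\n")
        fh.write("state\n")
        np.savetxt(fh, np.asarray(labels, dtype=int), fmt="%d")


def read_discrete(path):
    starts = [0]
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            _, _, val = first[1:].partition(":")
            starts = [int(s) for s in val.split(",")]
            fh.readline()  # header
        else:
            fh.seek(0)
        labels = np.loadtxt(fh, dtype=int)
    return np.atleast_1d(labels), starts


def write_pmf(profile, path) -> None:
    df = pd.DataFrame({"cv": profile.centers, "free_energy": profile.values,
                       "stderr": profile.errors})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# JSON / YAML
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """Read a run configuration from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
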