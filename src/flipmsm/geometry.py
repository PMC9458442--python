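"""Geometric observables for base-flipping analysis.

Centers of mass, COM separation, the flip pseudodihedral over four centers
of mass (flanking base pairs, flanking phosphate groups, flipping pyrimidine
ring), plain atomic torsions, hydrogen-bond occupancy, RMSD after optimal
superposition and per-atom/per-residue RMSF.

Angles follow the IUPAC torsion convention (signed atan2, wrapped to
(-180, 180], positive for clockwise rotation of the far bond viewed along
the central bond).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import Trajectory


@dataclass
class AtomSelection:
    """A group of atoms with masses, used for center-of-mass observables."""

    indices: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.indices.size == 0:
            raise ValueError("empty atom selection")
        if np.unique(self.indices).size != self.indices.size:
            raise ValueError("atom indices must be unique")
        if self.masses.shape != self.indices.shape:
            raise ValueError("one mass per atom index required")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")

    @classmethod
    def from_trajectory(cls, traj: Trajectory, indices) -> "AtomSelection":
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= traj.n_atoms):
            raise ValueError("atom index out of trajectory bounds")
        return cls(indices=idx, masses=traj.masses[idx])


@dataclass
class CPDbSpec:
    """Four COM groups defining the flip pseudodihedral p1-p2-p3-p4.

    p1: the two flanking base pairs; p2, p3: the flanking phosphate groups;
    p4: the six-membered ring of the flipping pyrimidine.  Groups may share
    atoms but must each be non-empty.
    """

    p1: AtomSelection
    p2: AtomSelection
    p3: AtomSelection
    p4: AtomSelection

    def selections(self):
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass
class HBondSpec:
    """Donor-hydrogen-acceptor triple with geometric cutoffs."""

    donor: int
    hydrogen: int
    acceptor: int
    distance_cutoff: float = 3.5   # donor-acceptor, Angstrom
    angle_cutoff: float = 120.0    # D-H-A angle, degrees

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0.0 < self.angle_cutoff <= 180.0:
            raise ValueError("angle cutoff must lie in (0, 180]")


def cpdb_spec_for_duplex(traj: Trajectory, lesion_resid: int,
                         lesion_chain: str = "A") -> CPDbSpec:
    """Default flip-pseudodihedral groups for a duplex with paired numbering.

    Assumes chain-A residue r pairs with chain-B residue 2n+1-r (n base
    pairs).  p1: heavy atoms of the base pairs immediately 5' and 3' of the
    lesion (both strands); p2/p3: the flanking phosphate groups on the
    lesion strand; p4: the six-membered ring of the lesion.  Fully
    overridable by constructing a :class:`CPDbSpec` directly.
    """
    n = int(traj.res_ids[traj.chain_ids == lesion_chain].max())
    partner_of = lambda r: 2 * n + 1 - r
    p1_idx = np.concatenate([
        traj.select(res_id=r, heavy_only=True)
        for bp in (lesion_resid - 1, lesion_resid + 1)
        for r in (bp, partner_of(bp))
    ])
    def phosphate(resid):
        sel = traj.select(res_id=resid, chain_id=lesion_chain)
        return sel[traj.atom_names[sel] == "P"]
    ring = traj.select(res_id=lesion_resid, chain_id=lesion_chain, heavy_only=True)
    ring = ring[traj.atom_names[ring] != "P"]
    make = lambda idx: AtomSelection.from_trajectory(traj, idx)
    return CPDbSpec(make(p1_idx), make(phosphate(lesion_resid - 1)),
                    make(phosphate(lesion_resid + 1)), make(ring))


def center_of_mass(frame: np.ndarray, sel: AtomSelection) -> np.ndarray:
    """Mass-weighted mean position sum(m_i r_i)/sum(m_i) of a selection."""
    frame = np.asarray(frame, dtype=float)
    r = frame[sel.indices]
    return sel.masses @ r / sel.masses.sum()


def com_distance(frame: np.ndarray, sel_a: AtomSelection, sel_b: AtomSelection) -> float:
    """Euclidean distance between the COMs of two selections (Angstrom)."""
    return float(np.linalg.norm(center_of_mass(frame, sel_a) - center_of_mass(frame, sel_b)))


def _torsion_from_points(p1, p2, p3, p4) -> float:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12:
        raise ValueError("undefined torsion: consecutive points coincide")
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("undefined torsion: three consecutive points are colinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / norm_b2
    ang = np.degrees(np.arctan2(y, x))
    # wrap to (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def cpdb(frame: np.ndarray, spec: CPDbSpec) -> float:
    """Flip pseudodihedral (degrees) over the four COM points p1-p2-p3-p4."""
    pts = [center_of_mass(frame, s) for s in spec.selections()]
    return _torsion_from_points(*pts)


def torsion(frame: np.ndarray, atoms) -> float:
    """Torsion angle (degrees) over four individual atoms."""
    atoms = np.asarray(atoms, dtype=int)
    if atoms.shape != (4,) or np.unique(atoms).size != 4:
        raise ValueError("torsion requires four distinct atom indices")
    frame = np.asarray(frame, dtype=float)
    return _torsion_from_points(*frame[atoms])


def cpdb_series(traj: Trajectory, spec: CPDbSpec) -> np.ndarray:
    """Flip pseudodihedral per frame."""
    return np.array([cpdb(f, spec) for f in traj.coords])


def hbond_occupancy(traj: Trajectory, spec: HBondSpec) -> float:
    """Fraction of frames satisfying the H-bond distance AND angle criteria.

    A frame counts when the donor-acceptor distance is <= distance_cutoff
    and the donor-hydrogen-acceptor angle is >= angle_cutoff.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    for idx in (spec.donor, spec.hydrogen, spec.acceptor):
        if not 0 <= idx < traj.n_atoms:
            raise ValueError(f"atom index {idx} out of bounds")
    d = traj.coords[:, spec.donor]
    h = traj.coords[:, spec.hydrogen]
    a = traj.coords[:, spec.acceptor]
    da = np.linalg.norm(d - a, axis=1)
    v1 = d - h
    v2 = a - h
    cosang = np.sum(v1 * v2, axis=1) / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ok = (da <= spec.distance_cutoff) & (ang >= spec.angle_cutoff)
    return float(ok.mean())


# ---------------------------------------------------------------------------
# Superposition, RMSD, RMSF
# ---------------------------------------------------------------------------

def _check_superposable(coords: np.ndarray):
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    c = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-8) < 2:
        raise ValueError("superposition needs at least 3 non-colinear atoms")


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid-body fit of ``mobile`` onto ``reference`` (Kabsch).

    Returns the transformed coordinates.
    """
    _check_superposable(reference)
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    return rot.apply(mobile - mc) + rc


def rmsd_series(traj: Trajectory, reference: np.ndarray, selection=None) -> np.ndarray:
    """Per-frame RMSD (Angstrom) to a reference after optimal superposition."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    ref = np.asarray(reference, dtype=float)[sel] if np.asarray(reference).shape[0] == traj.n_atoms \
        else np.asarray(reference, dtype=float)
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.coords):
        fitted = superpose(frame[sel], ref)
        out[i] = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1)))
    return out


def rmsf(traj: Trajectory, selection=None, n_iter: int = 3) -> np.ndarray:
    """Per-atom RMSF (Angstrom) about the time-mean structure.

    All frames are superposed onto the time-averaged structure (iterated a
    few times so the average is self-consistent), then the root mean square
    deviation of each atom about its mean position is reported.
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    frames = traj.coords[:, sel]
    mean = frames[0]
    fitted = frames
    for _ in range(n_iter):
        fitted = np.array([superpose(f, mean) for f in frames])
        mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def rmsf_per_residue(traj: Trajectory, selection=None) -> dict:
    """Mass-weighted mean RMSF per residue, keyed by (chain_id, res_id)."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection, dtype=int)
    per_atom = rmsf(traj, sel)
    out = {}
    keys = list(zip(traj.chain_ids[sel], traj.res_ids[sel]))
    for key in dict.fromkeys(keys):
        mask = np.array([k == key for k in keys])
        w = traj.masses[sel][mask]
        out[key] = float(w @ per_atom[mask] / w.sum())
    return out
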