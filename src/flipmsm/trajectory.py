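"""In-memory trajectory container.

Coordinates are stored in Angstrom as a ``(n_frames, n_atoms, 3)`` array
together with per-atom PDB-style labels and per-frame segment bookkeeping.
Multiple independent simulations are concatenated along the frame axis with
their start indices recorded in ``segment_starts`` so that time-lagged
statistics never straddle a segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Masses (amu) for the elements the toy systems and typical nucleic-acid
# heavy atoms use.  Hydrogens are retained because H-bond geometry needs them.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
    "S": 32.06,
}


def element_masses(elements: np.ndarray) -> np.ndarray:
    """Look up atomic masses (amu) for an array of element symbols."""
    try:
        return np.array([ATOMIC_MASSES[e.strip().upper()] for e in elements])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown element symbol: {exc.args[0]!r}") from None


@dataclass
class Trajectory:
    """Frames x atoms Cartesian coordinates with atom/residue labels.

    Parameters
    ----------
    coords : ndarray, shape (F, A, 3)
        Cartesian coordinates in Angstrom.
    atom_names, res_names, elements : ndarray of str, shape (A,)
    res_ids : ndarray of int, shape (A,)
    chain_ids : ndarray of str, shape (A,)
    masses : ndarray of float, shape (A,), amu
    dt : float
        Time between frames (arbitrary units; the pipeline works in frames).
    segment_starts : list of int
        Start index of each independent trajectory segment; first is 0.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray = None
    dt: float = 1.0
    segment_starts: list = field(default_factory=lambda: [0])

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        for name in ("atom_names", "res_ids", "res_names", "chain_ids", "elements"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length {n_atoms}, got {arr.shape}")
            setattr(self, name, arr)
        if self.masses is None:
            self.masses = element_masses(self.elements)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be strictly positive")
        if not self.segment_starts or self.segment_starts[0] != 0:
            raise ValueError("segment_starts must begin with 0")
        if any(b >= c for b, c in zip(self.segment_starts, self.segment_starts[1:])):
            raise ValueError("segment_starts must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, res_id=None, chain_id=None, res_name=None,
               heavy_only: bool = False) -> np.ndarray:
        """Return 0-based atom indices matching the given residue criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if res_id is not None:
            mask &= self.res_ids == res_id
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if res_name is not None:
            mask &= self.res_names == res_name
        if heavy_only:
            mask &= self.elements != "H"
        return np.flatnonzero(mask)

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame ``i`` as an (A, 3) array."""
        return self.coords[i]

    @staticmethod
    def concatenate(trajs: list["Trajectory"]) -> "Trajectory":
        """Concatenate independent trajectories, recording segment boundaries."""
        if not trajs:
            raise ValueError("nothing to concatenate")
        ref = trajs[0]
        for k, t in enumerate(trajs[1:], start=1):
            if t.n_atoms != ref.n_atoms:
                raise ValueError(
                    f"atom count mismatch: trajectory 0 has {ref.n_atoms} atoms, "
                    f"trajectory {k} has {t.n_atoms}"
                )
        starts, off = [], 0
        for t in trajs:
            starts.extend(b + off for b in t.segment_starts)
            off += t.n_frames
        return Trajectory(
            coords=np.concatenate([t.coords for t in trajs], axis=0),
            atom_names=ref.atom_names, res_ids=ref.res_ids,
            res_names=ref.res_names, chain_ids=ref.chain_ids,
            elements=ref.elements, masses=ref.masses, dt=ref.dt,
            segment_starts=starts,
        )
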