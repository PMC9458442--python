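"""Collective-variable operations: closed-form cases, brute-force oracles,
and rigid-motion invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import flipmsm as fm
from flipmsm.trajectory import Trajectory


def make_traj(coords):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return Trajectory(coords=coords,
                      atom_names=np.array([f"C{i}" for i in range(n)]),
                      res_ids=np.ones(n, dtype=int),
                      res_names=np.full(n, "LIG"),
                      chain_ids=np.full(n, "A"),
                      elements=np.full(n, "C"))


def sel(indices, masses=None):
    indices = np.asarray(indices)
    masses = np.ones(len(indices)) if masses is None else np.asarray(masses)
    return fm.AtomSelection(indices=indices, masses=masses)


class TestCenterOfMass:
    def test_midpoint_and_weighted_mean(self):
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert np.allclose(fm.center_of_mass(frame, sel([0, 1])), [1, 0, 0])
        assert np.allclose(fm.center_of_mass(frame, sel([0, 1], [1, 3])),
                           [1.5, 0, 0])

    def test_matches_explicit_summation(self, rng):
        frame = rng.normal(size=(5, 3))
        masses = rng.uniform(1, 20, size=5)
        expected = sum(m * r for m, r in zip(masses, frame)) / masses.sum()
        got = fm.center_of_mass(frame, sel(range(5), masses))
        assert np.allclose(got, expected, atol=1e-12)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fm.AtomSelection(indices=np.array([], dtype=int), masses=np.array([]))


class TestComDistance:
    def test_identical_and_pythagorean(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert fm.com_distance(frame, sel([0]), sel([0])) == 0.0
        assert fm.com_distance(frame, sel([0]), sel([1])) == pytest.approx(5.0)

    def test_symmetry_and_composition(self, rng):
        frame = rng.normal(size=(6, 3))
        a, b = sel([0, 1, 2]), sel([3, 4, 5])
        d = fm.com_distance(frame, a, b)
        assert d == fm.com_distance(frame, b, a)
        assert d == pytest.approx(np.linalg.norm(
            fm.center_of_mass(frame, a) - fm.center_of_mass(frame, b)), abs=1e-12)

    def test_triangle_inequality(self, rng):
        frame = rng.normal(size=(9, 3))
        a, b, c = sel([0, 1, 2]), sel([3, 4, 5]), sel([6, 7, 8])
        assert fm.com_distance(frame, a, c) <= (
            fm.com_distance(frame, a, b) + fm.com_distance(frame, b, c) + 1e-12)


class TestTorsions:
    def test_colinear_is_undefined(self):
        frame = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="torsion"):
            fm.torsion(frame, [0, 1, 2, 3])

    def test_planar_cis_and_quarter_turn(self):
        frame = np.array([[0.0, 1, 0], [0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0]])
        assert fm.torsion(frame, [0, 1, 2, 3]) == pytest.approx(0.0, abs=1e-10)
        frame[3] = [1.0, 0, 1]
        ang = fm.torsion(frame, [0, 1, 2, 3])
        assert abs(ang) == pytest.approx(90.0, abs=1e-10)
        # IUPAC sign via explicit vector brute force
        b1, b2, b3 = (frame[1] - frame[0], frame[2] - frame[1], frame[3] - frame[2])
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
        assert np.sign(ang) == np.sign(np.degrees(np.arctan2(y, np.dot(n1, n2))))

    def test_trans_and_mirror_image(self):
        frame = np.array([[0.0, 1, 0], [0.0, 0, 0], [1.0, 0, 0], [1.0, -1, 0]])
        assert fm.torsion(frame, [0, 1, 2, 3]) == pytest.approx(180.0, abs=1e-10)
        skew = np.array([[0.0, 1, 0.3], [0.0, 0, 0], [1.0, 0, 0], [1.0, -1, 0.4]])
        mirrored = skew * np.array([1.0, 1.0, -1.0])
        assert fm.torsion(skew, [0, 1, 2, 3]) == pytest.approx(
            -fm.torsion(mirrored, [0, 1, 2, 3]), abs=1e-10)

    def test_cpdb_reduces_to_torsion_on_singletons(self, rng):
        frame = rng.normal(size=(4, 3)) * 3.0
        spec = fm.CPDbSpec(*[sel([i]) for i in range(4)])
        assert fm.cpdb(frame, spec) == pytest.approx(
            fm.torsion(frame, [0, 1, 2, 3]), abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        frame = rng.normal(size=(8, 3)) * 4.0
        spec = fm.CPDbSpec(sel([0, 1]), sel([2, 3]), sel([4, 5]), sel([6, 7]))
        ref = fm.cpdb(frame, spec)
        for _ in range(5):
            rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            shift = rng.normal(size=3) * 10
            moved = frame @ rot.T + shift
            assert fm.cpdb(moved, spec) == pytest.approx(ref, abs=1e-9)
            assert fm.torsion(moved[:4][None][0], [0, 1, 2, 3]) == pytest.approx(
                fm.torsion(frame, [0, 1, 2, 3]), abs=1e-9)


class TestHbondOccupancy:
    def build(self, n_good, n_bad):
        # good geometry: linear D-H...A, 2.9 A; bad: bent far pair
        good = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0, 0]])
        bad = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 4.5, 0]])
        frames = [good] * n_good + [bad] * n_bad
        return make_traj(np.array(frames))

    def test_all_and_half(self):
        spec = fm.HBondSpec(donor=0, hydrogen=1, acceptor=2)
        assert fm.hbond_occupancy(self.build(4, 0), spec) == 1.0
        assert fm.hbond_occupancy(self.build(5, 5), spec) == 0.5

    def test_matches_per_frame_boolean_oracle(self, rng):
        coords = rng.normal(size=(100, 3, 3)) * 2.0
        traj = make_traj(coords)
        spec = fm.HBondSpec(donor=0, hydrogen=1, acceptor=2,
                            distance_cutoff=3.0, angle_cutoff=100.0)
        expect = 0
        for f in coords:
            d = np.linalg.norm(f[0] - f[2])
            v1, v2 = f[0] - f[1], f[2] - f[1]
            ang = np.degrees(np.arccos(np.clip(
                v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            expect += (d <= 3.0) and (ang >= 100.0)
        assert fm.hbond_occupancy(traj, spec) == expect / 100

    def test_monotone_in_cutoffs(self, rng):
        traj = make_traj(rng.normal(size=(200, 3, 3)) * 2.0)
        occ_d = [fm.hbond_occupancy(traj, fm.HBondSpec(0, 1, 2, distance_cutoff=c,
                                                       angle_cutoff=110.0))
                 for c in (2.0, 3.0, 4.0, 6.0)]
        assert all(a <= b for a, b in zip(occ_d, occ_d[1:]))
        occ_a = [fm.hbond_occupancy(traj, fm.HBondSpec(0, 1, 2, distance_cutoff=4.0,
                                                       angle_cutoff=c))
                 for c in (60.0, 100.0, 140.0)]
        assert all(a >= b for a, b in zip(occ_a, occ_a[1:]))


class TestRMSD:
    def test_identical_and_rigidly_moved_frames(self, rng):
        base = rng.normal(size=(10, 3)) * 3.0
        rot = Rotation.random(random_state=5).as_matrix()
        frames = np.stack([base, base + 5.0, base @ rot.T + [1, 2, 3]])
        traj = make_traj(frames)
        r = fm.rmsd_series(traj, base)
        assert np.allclose(r, 0.0, atol=1e-8)

    def test_pure_displacement_closed_form(self, rng):
        # displacements chosen with zero net translation and (near-)zero
        # torque so the optimal superposition is the identity
        base = rng.normal(size=(30, 3)) * 5.0
        disp = rng.normal(size=(30, 3))
        disp -= disp.mean(axis=0)
        traj = make_traj(np.stack([base, base + disp]))
        expected = np.sqrt(np.mean(np.sum(disp**2, axis=1)))
        got = fm.rmsd_series(traj, base)[1]
        assert got <= expected + 1e-9      # fitting can only reduce it
        assert got == pytest.approx(expected, rel=0.05)

    def test_too_few_atoms_rejected(self):
        traj = make_traj(np.zeros((1, 2, 3)))
        with pytest.raises(ValueError, match="superposition"):
            fm.rmsd_series(traj, traj.coords[0])


class TestRMSF:
    def test_static_trajectory_has_zero_fluctuation(self, rng):
        base = rng.normal(size=(6, 3))
        traj = make_traj(np.stack([base] * 5))
        assert np.allclose(fm.rmsf(traj), 0.0, atol=1e-10)

    def test_one_mobile_atom_dominates(self, rng):
        base = rng.normal(size=(25, 3)) * 4.0
        frames = np.stack([base.copy() for _ in range(40)])
        frames[:, 0, 0] += rng.normal(scale=1.5, size=40)
        traj = make_traj(frames)
        f = fm.rmsf(traj)
        assert f[0] > 3 * f[1:].max()

    def test_per_residue_aggregation(self, rng):
        frames = rng.normal(size=(10, 4, 3))
        traj = make_traj(frames)
        per_res = fm.rmsf_per_residue(traj)
        assert set(per_res) == {("A", 1)}
        w = traj.masses
        assert per_res[("A", 1)] == pytest.approx(
            float(w @ fm.rmsf(traj) / w.sum()))
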