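"""MSM estimation: clustering, counting, reversible MLE, implied
timescales, Chapman-Kolmogorov validation, PCCA+ and free energies."""

import numpy as np
import pytest

import flipmsm as fm
from flipmsm.msm import KB_KCAL, _spectral


class TestKmeans:
    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(size=(100, 2)) * 0.1
        b = rng.normal(size=(100, 2)) * 0.1 + 10.0
        fs = fm.FeatureSeries(values=np.vstack([a, b]))
        out = fm.kmeans_cluster(fs, k=2, seed=0)
        first, second = out.labels[:100], out.labels[100:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_one_point_per_cluster_zero_inertia(self, rng):
        fs = fm.FeatureSeries(values=rng.normal(size=(8, 2)))
        out = fm.kmeans_cluster(fs, k=8, seed=0)
        assert out.inertia == pytest.approx(0.0, abs=1e-12)

    def test_beats_random_assignments(self, rng):
        x = np.vstack([rng.normal(size=(60, 2)) + c
                       for c in ([0, 0], [6, 0], [0, 6], [6, 6], [3, 3])])
        fs = fm.FeatureSeries(values=x)
        out = fm.kmeans_cluster(fs, k=5, seed=1)
        for _ in range(10):
            lab = rng.integers(0, 5, size=len(x))
            inertia = sum(np.sum((x[lab == j] - x[lab == j].mean(axis=0)) ** 2)
                          for j in range(5) if np.any(lab == j))
            assert out.inertia <= inertia

    def test_k_below_two_rejected(self, rng):
        fs = fm.FeatureSeries(values=rng.normal(size=(10, 2)))
        with pytest.raises(ValueError, match="microstates"):
            fm.kmeans_cluster(fs, k=1)

    def test_duplicate_frames_handled(self):
        fs = fm.FeatureSeries(values=np.tile([[1.0, 2.0]], (30, 1)))
        out = fm.kmeans_cluster(fs, k=3, seed=0)
        assert out.labels.shape == (30,)


class TestCounting:
    def test_hand_counted_examples(self):
        c = fm.count_transitions([0, 1, 0, 1], 1)
        assert np.array_equal(c, [[0, 2], [1, 0]])
        c = fm.count_transitions([0, 0, 0], 2, n_states=2)
        assert np.array_equal(c, [[1, 0], [0, 0]])

    def test_matches_pair_loop_oracle(self, rng):
        labels = rng.integers(0, 4, size=200)
        starts = [0, 80, 150]
        tau = 3
        c = fm.count_transitions(labels, tau, starts)
        expect = np.zeros((4, 4))
        for a, b in zip(starts, starts[1:] + [200]):
            for t in range(a, b - tau):
                expect[labels[t], labels[t + tau]] += 1
        assert np.array_equal(c, expect)

    def test_lag_exceeding_segments_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            fm.count_transitions([0, 1, 0], 5)


class TestLargestConnectedSet:
    def test_block_diagonal_picks_big_block(self):
        c = np.zeros((5, 5))
        c[np.ix_([0, 1, 2], [0, 1, 2])] = 1
        c[np.ix_([3, 4], [3, 4])] = 1
        assert fm.largest_connected_set(c).tolist() == [0, 1, 2]

    def test_fully_connected_keeps_all(self, rng):
        c = rng.uniform(0.1, 1.0, size=(6, 6))
        assert fm.largest_connected_set(c).tolist() == list(range(6))

    def test_matches_brute_force_scc_oracle(self, rng):
        for _ in range(20):
            c = (rng.random((7, 7)) < 0.18).astype(float)
            got = set(fm.largest_connected_set(c).tolist())
            # brute force: i~j when i reaches j and j reaches i
            reach = (c > 0) | np.eye(7, dtype=bool)
            for _ in range(7):
                reach = reach | (reach @ reach)
            mutual = reach & reach.T
            comps = {frozenset(np.flatnonzero(mutual[i])) for i in range(7)}
            assert got in [set(s) for s in comps
                           if len(s) == max(len(x) for x in comps)]


class TestReversibleMLE:
    def test_symmetric_counts(self):
        t, pi = fm.reversible_mle(np.full((2, 2), 5.0))
        assert np.allclose(t, 0.5) and np.allclose(pi, 0.5)

    def test_two_state_closed_form(self):
        # any 2-state chain satisfies detailed balance, so the reversible
        # MLE coincides with the row-normalized counts
        c = np.array([[90.0, 10.0], [20.0, 80.0]])
        t, pi = fm.reversible_mle(c)
        assert np.allclose(t, c / c.sum(axis=1, keepdims=True), atol=1e-8)
        assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-8)

    def test_detailed_balance_and_stationarity(self, rng):
        for _ in range(5):
            c = rng.integers(1, 50, size=(4, 4)).astype(float)
            t, pi = fm.reversible_mle(c)
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-10)
            assert np.allclose(pi @ t, pi, atol=1e-10)
            assert np.max(np.abs(pi[:, None] * t - (pi[:, None] * t).T)) < 1e-8

    def test_likelihood_beats_symmetrized_estimate(self, rng):
        c = rng.integers(1, 60, size=(4, 4)).astype(float)
        t, _ = fm.reversible_mle(c)
        sym = c + c.T
        t_sym = sym / sym.sum(axis=1, keepdims=True)
        ll = lambda m: np.sum(c[m > 0] * np.log(m[m > 0]))
        assert ll(t) >= ll(t_sym) - 1e-9

    def test_recovers_known_five_state_chain(self, five_state_chain):
        t_true, seq = five_state_chain
        model = fm.estimate_msm(seq, 1)
        assert model.n_states == 5
        assert np.max(np.abs(model.transition_matrix - t_true)) < 0.01
        pi_true = _stationary(t_true)
        assert np.max(np.abs(model.stationary - pi_true)) < 0.005


def _stationary(t):
    vals, vecs = np.linalg.eig(t.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
    return v / v.sum()


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])  # lambda_2 = 0.8
        seq = fm.sample_markov_chain(
            fm.MarkovChainSpec(transition_matrix=t, n_steps=300_000, seed=8))[0]
        out = fm.implied_timescales(seq, [1, 2], n_timescales=1)
        assert out["timescales"][0, 0] == pytest.approx(-1 / np.log(0.8), rel=0.05)

    def test_markovian_chain_lag_invariant(self):
        t = np.array([[0.95, 0.05], [0.05, 0.95]])
        seq = fm.sample_markov_chain(
            fm.MarkovChainSpec(transition_matrix=t, n_steps=500_000, seed=9))[0]
        out = fm.implied_timescales(seq, [1, 2, 4], n_timescales=1)
        ts = out["timescales"][:, 0]
        assert np.max(np.abs(ts - ts[0])) / ts[0] < 0.1
        assert out["plateau"][1:].all()

    def test_eigenvalue_near_one_is_infinity_safe(self):
        model = fm.MarkovModel(lag=1, counts=None, active_set=np.arange(2),
                               transition_matrix=np.eye(2),
                               stationary=np.array([0.5, 0.5]),
                               eigenvalues=np.array([1.0, 1.0]),
                               right_eigenvectors=None, left_eigenvectors=None)
        assert np.isfinite(model.timescales(1)[0])  # huge but not inf/raise


class TestChapmanKolmogorov:
    def test_markov_data_passes(self, five_state_chain):
        _, seq = five_state_chain
        ck = fm.chapman_kolmogorov(seq, 1, [[0, 1], [2], [3, 4]],
                                   factors=(1, 2, 4), n_bootstrap=50, seed=0)
        assert ck.passed

    def test_factor_one_identity(self, five_state_chain):
        _, seq = five_state_chain
        ck = fm.chapman_kolmogorov(seq, 1, [[0, 1, 2], [3, 4]], factors=(1,),
                                   n_bootstrap=10, seed=0)
        assert np.allclose(ck.predicted[0], ck.estimated[0])

    def test_period_two_forcing_fails(self):
        # deterministic alternation with tiny noise is maximally non-Markovian
        # at even multiples of the lag
        rng = np.random.default_rng(0)
        seq = np.arange(100_000) % 2
        flip = rng.random(100_000) < 0.02
        seq = np.where(flip, 1 - seq, seq)
        ck = fm.chapman_kolmogorov(seq, 1, [[0], [1]], factors=(1, 2),
                                   n_bootstrap=50, seed=1)
        assert not ck.passed


class TestPCCA:
    def test_two_block_chain_recovers_blocks(self):
        eps = 1e-3
        t = np.array([
            [0.49, 0.49, eps, 0.02 - eps],
            [0.49, 0.49, eps, 0.02 - eps],
            [eps, 0.02 - eps, 0.49, 0.49],
            [eps, 0.02 - eps, 0.49, 0.49],
        ])
        t = t / t.sum(axis=1, keepdims=True)
        pi = _stationary(t)
        lam, right, left = _spectral(t, pi)
        model = fm.MarkovModel(lag=1, counts=None, active_set=np.arange(4),
                               transition_matrix=t, stationary=pi,
                               eigenvalues=lam, right_eigenvectors=right,
                               left_eigenvectors=left)
        part = fm.pcca_plus(model, 2)
        assert part.crisp[0] == part.crisp[1]
        assert part.crisp[2] == part.crisp[3]
        assert part.crisp[0] != part.crisp[2]

    def test_full_resolution_identity_memberships(self, rng):
        c = rng.integers(5, 40, size=(3, 3)).astype(float)
        model = fm.estimate_msm(
            fm.sample_markov_chain(fm.MarkovChainSpec(
                transition_matrix=np.array([[0.8, 0.1, 0.1],
                                            [0.1, 0.8, 0.1],
                                            [0.1, 0.1, 0.8]]),
                n_steps=50_000, seed=12))[0], 1)
        part = fm.pcca_plus(model, 3)
        perm = part.memberships[np.argsort(part.crisp)]
        assert np.allclose(np.sort(part.crisp), [0, 1, 2])
        assert np.allclose(part.memberships.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(np.sort(perm, axis=0), np.sort(np.eye(3), axis=0),
                           atol=0.05)

    def test_five_basin_macrostate_recovery(self, five_basin_run):
        from tests.conftest import macrostate_agreement
        assert macrostate_agreement(five_basin_run) >= 0.90

    def test_oversized_macrostate_count_rejected(self, five_state_chain):
        _, seq = five_state_chain
        model = fm.estimate_msm(seq, 1)
        with pytest.raises(ValueError):
            fm.pcca_plus(model, 6)


class TestFreeEnergy:
    def test_equal_weights_degenerate(self):
        dg = fm.macrostate_free_energy([0.5, 0.5])
        assert np.allclose(dg, 0.0)

    def test_unit_mode_log_weight(self):
        w = np.array([np.e**-1 / (1 + np.e**-1), 1 / (1 + np.e**-1)])
        dg = fm.macrostate_free_energy(w, temperature=1.0, kB=1.0)
        assert dg[0] == pytest.approx(1.0, abs=1e-12)
        assert dg[1] == 0.0

    def test_matches_direct_formula(self, rng):
        pi = rng.dirichlet(np.ones(20))
        crisp = rng.integers(0, 4, size=20)
        from flipmsm.msm import macrostate_weights
        w = macrostate_weights(crisp, pi)
        dg = fm.macrostate_free_energy(w, temperature=298.0)
        expect = np.array([-KB_KCAL * 298.0 * np.log(pi[crisp == i].sum())
                           for i in range(4)])
        expect -= expect.min()
        assert np.allclose(dg, expect, atol=1e-12)

    def test_invariant_under_weight_rescaling(self, rng):
        w = rng.uniform(0.1, 1.0, size=5)
        assert np.allclose(fm.macrostate_free_energy(w),
                           fm.macrostate_free_energy(10.0 * w), atol=1e-12)

    def test_empty_macrostate_flagged_infinite(self):
        dg = fm.macrostate_free_energy([0.7, 0.0, 0.3])
        assert np.isinf(dg[1]) and np.isfinite(dg[[0, 2]]).all()
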