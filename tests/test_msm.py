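"""MSM estimation, spectral/metastable analysis and binding observables."""

import numpy as np
import pytest

from gomsm.constants import KB
from gomsm.msm import (
    CountMatrix,
    DiscreteTrajectory,
    MarkovModel,
    binding_observables,
    bootstrap_errors,
    bulk_volume,
    count_transitions,
    estimate_transition_matrix,
    implied_timescales,
    mfpt_between_sets,
    pcca_assign,
    pmf_binding_constant,
    stationary_distribution,
)
from gomsm.synthetic import birth_death_reference, sample_markov_chain


def _model_from_T(T, lag_time=1.0, reversible=True):
    pi = stationary_distribution(T)
    evals = np.sort(np.linalg.eigvals(T).real)[::-1]
    return MarkovModel(T=T, lag_time=lag_time, pi=pi, eigenvalues=evals,
                       active_set=np.arange(len(T)), reversible=reversible)


class TestCounting:
    def test_hand_enumerated_counts(self):
        d = DiscreteTrajectory([0, 0, 1, 1, 0], 1.0)
        cm = count_transitions([d], 1)
        assert cm.counts.tolist() == [[1, 1], [1, 1]]

    def test_additivity_over_trajectories(self):
        d = DiscreteTrajectory([0, 1, 0, 1, 1], 1.0)
        c1 = count_transitions([d], 1).counts
        c2 = count_transitions([d, d], 1).counts
        assert np.array_equal(c2, 2 * c1)

    def test_lag_must_be_shorter_than_trajectory(self):
        d = DiscreteTrajectory([0, 1, 0], 1.0)
        with pytest.raises(ValueError):
            count_transitions([d], 3)


class TestEstimation:
    def test_symmetric_counts_both_modes(self):
        cm = CountMatrix(np.array([[8.0, 2.0], [2.0, 8.0]]), 1, 1.0)
        for rev in (True, False):
            m = estimate_transition_matrix(cm, reversible=rev)
            assert np.allclose(m.T, [[0.8, 0.2], [0.2, 0.8]], atol=1e-10)

    def test_disconnected_state_dropped(self):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 5
        C[0, 0] = C[1, 1] = 5
        C[2, 2] = 3  # self-loop island
        m = estimate_transition_matrix(CountMatrix(C, 1, 1.0))
        assert m.active_set.tolist() == [0, 1]

    def test_reversible_estimate_satisfies_detailed_balance(self):
        rng = np.random.default_rng(0)
        C = rng.integers(1, 30, (4, 4)).astype(float)
        m = estimate_transition_matrix(CountMatrix(C, 1, 1.0), reversible=True)
        flux = m.pi[:, None] * m.T
        assert np.max(np.abs(flux - flux.T)) < 1e-8

    def test_estimator_consistency_on_known_chain(self):
        ref = birth_death_reference([0.0, 1.0, 0.3, 1.5, 0.7])
        errs = []
        for n in (10_000, 100_000, 1_000_000):
            traj = sample_markov_chain(ref.T, n, seed=123)
            m = estimate_transition_matrix(
                count_transitions([DiscreteTrajectory(traj, 1.0)], 1)
            )
            errs.append(np.max(np.abs(m.T - ref.T)))
        assert errs[-1] < 0.01
        assert errs[2] < errs[0]


class TestStationary:
    def test_symmetric_two_state(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert np.allclose(pi, [0.5, 0.5])

    def test_asymmetric_two_state_balance(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert np.allclose(pi, [2 / 3, 1 / 3])

    def test_reducible_matrix_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.eye(2))


class TestTimescales:
    def test_closed_form_conversions(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])  # lambda2 = 0.8
        m = _model_from_T(T, lag_time=12.0)
        m.eigenvalues = np.array([1.0, np.exp(-1.0)])
        ts, flags = implied_timescales(m, 1)
        assert ts[0] == pytest.approx(12.0)
        m.eigenvalues = np.array([1.0, 0.5])
        ts, _ = implied_timescales(m, 1)
        assert ts[0] == pytest.approx(-1.0 / np.log(0.5) * 12.0 / 12.0 * 12.0)

    def test_unit_eigenvalue_flagged_infinite(self):
        m = _model_from_T(np.array([[0.9, 0.1], [0.1, 0.9]]), lag_time=1.0)
        m.eigenvalues = np.array([1.0, 1.0])
        ts, flags = implied_timescales(m, 1)
        assert np.isinf(ts[0]) and flags[0]

    def test_k_bound(self):
        m = _model_from_T(np.array([[0.9, 0.1], [0.1, 0.9]]))
        with pytest.raises(ValueError):
            implied_timescales(m, 2)


class TestPCCA:
    def _block_matrix(self, eps=1e-3):
        T = np.array([
            [0.89, 0.11 - eps, eps / 2, eps / 2],
            [0.11 - eps, 0.89, eps / 2, eps / 2],
            [eps / 2, eps / 2, 0.79, 0.21 - eps],
            [eps / 2, eps / 2, 0.21 - eps, 0.79],
        ])
        T /= T.sum(axis=1, keepdims=True)
        return T

    def test_two_block_recovery(self):
        m = _model_from_T(self._block_matrix())
        assign = pcca_assign(m, 2)
        labels = assign.crisp_labels
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert np.allclose(assign.memberships.sum(axis=1), 1.0)

    def test_m_equals_n_is_identity_up_to_permutation(self):
        m = _model_from_T(self._block_matrix())
        assign = pcca_assign(m, 4)
        chi = assign.memberships
        perm = np.argmax(chi, axis=0)
        assert sorted(perm.tolist()) == [0, 1, 2, 3]
        assert np.allclose(chi[perm, np.arange(4)], 1.0, atol=1e-6)

    def test_m_of_one_rejected(self):
        m = _model_from_T(self._block_matrix())
        with pytest.raises(ValueError):
            pcca_assign(m, 1)


class TestMFPT:
    def test_two_state_geometric(self):
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        m = _model_from_T(T, lag_time=12.0)
        assert mfpt_between_sets(m, [0], [1]) == pytest.approx(120.0)

    def test_absorbing_target_in_one_step(self):
        T = np.array([[0.0, 0.5, 0.5], [0.0, 0.5, 0.5], [0.2, 0.4, 0.4]])
        m = _model_from_T(T, lag_time=7.0, reversible=False)
        assert mfpt_between_sets(m, [0], [1, 2]) == pytest.approx(7.0)

    def test_matches_monte_carlo_passages(self):
        rng = np.random.default_rng(4)
        T = rng.dirichlet(np.ones(3) * 2, size=3)
        m = _model_from_T(T, lag_time=1.0, reversible=False)
        predicted = mfpt_between_sets(m, [0], [2])
        # Monte-Carlo oracle
        n_pass = 20_000
        cum = np.cumsum(T, axis=1)
        times = np.empty(n_pass)
        u = rng.random(n_pass * 200).reshape(n_pass, 200)
        for p in range(n_pass):
            s, t = 0, 0
            while s != 2:
                s = int(np.searchsorted(cum[s], u[p, t % 200] if t < 200 else rng.random()))
                t += 1
            times[p] = t
        mc = times.mean()
        se = times.std(ddof=1) / np.sqrt(n_pass)
        assert abs(predicted - mc) < 2.5 * se

    def test_matches_dense_solve_on_random_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            T = rng.dirichlet(np.ones(6), size=6)
            m = _model_from_T(T, lag_time=1.0, reversible=False)
            src, tgt = [0, 1], [4, 5]
            got = mfpt_between_sets(m, src, tgt)
            # dense oracle: solve (I - T_rest) tau = 1 over non-target states
            rest = [0, 1, 2, 3]
            tau = np.linalg.solve(np.eye(4) - T[np.ix_(rest, rest)], np.ones(4))
            w = m.pi[src] / m.pi[src].sum()
            want = float(w @ tau[:2])
            assert got == pytest.approx(want, abs=1e-10)

    def test_overlapping_sets_rejected(self):
        m = _model_from_T(np.array([[0.9, 0.1], [0.1, 0.9]]))
        with pytest.raises(ValueError):
            mfpt_between_sets(m, [0], [0, 1])


class TestVolumesAndObservables:
    def test_bulk_volume_production_geometry(self):
        assert bulk_volume(73.46, 29.0) == pytest.approx(1.558e6, rel=1e-3)

    def test_bulk_volume_limits(self):
        assert bulk_volume(10.0, 0.0) == pytest.approx(4 / 3 * np.pi * 1000)
        with pytest.raises(ValueError):
            bulk_volume(10.0, 10.0)

    def test_equal_populations_give_zero_free_energy(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        obs = binding_observables(_model_from_T(T, 1.0), [0], 73.46, 29.0, 300.0)
        assert obs.dG_b == pytest.approx(0.0, abs=1e-12)
        assert obs.K_eq == pytest.approx(obs.V)

    def test_two_state_identity_kon_koff(self):
        T = np.array([[0.95, 0.05], [0.2, 0.8]])
        obs = binding_observables(_model_from_T(T, 5.0), [0], 50.0, 10.0, 300.0)
        assert obs.k_on / obs.k_off == pytest.approx(obs.K_eq, rel=1e-12)

    def test_metastable_chain_identity_within_tolerance(self):
        """MFPT_off/MFPT_on ~ P_bound/P_unbound for a two-basin chain with
        large timescale separation, using basin cores (barrier state in
        neither set) as source/target."""
        ref = birth_death_reference([0.0, 0.5, 5.0, 0.8, 0.3])
        m = _model_from_T(ref.T, lag_time=1.0)
        ts = -1 / np.log(np.abs(m.eigenvalues[1:3]))
        assert ts[0] / ts[1] > 10  # genuine separation
        off = mfpt_between_sets(m, [0, 1], [3, 4])
        on = mfpt_between_sets(m, [3, 4], [0, 1])
        ratio = m.pi[:2].sum() / m.pi[2:].sum()
        assert off / on == pytest.approx(ratio, rel=0.05)

    def test_full_bound_set_rejected(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError):
            binding_observables(_model_from_T(T), [0, 1], 50.0, 10.0)

    def test_thermal_energy_at_300K(self):
        obs = binding_observables(
            _model_from_T(np.array([[0.9, 0.1], [0.1, 0.9]])), [0], 50.0, 10.0, 300.0
        )
        assert obs.kBT == pytest.approx(0.596, abs=5e-4)


class TestPMFBindingConstant:
    def test_flat_profile_is_sphere_volume(self):
        r = np.linspace(0, 12, 200)
        prof = np.column_stack([r, np.zeros_like(r)])
        K = pmf_binding_constant(prof, 10.0)
        assert K == pytest.approx(4 / 3 * np.pi * 1000, rel=1e-3)

    def test_high_barrier_suppresses_integral(self):
        kbt = KB * 300
        r = np.linspace(0, 12, 200)
        prof = np.column_stack([r, np.full_like(r, 50 * kbt)])
        with pytest.warns(RuntimeWarning):
            K = pmf_binding_constant(prof, 10.0)
        flat = 4 / 3 * np.pi * 1000
        assert K < 1e-15 * flat

    def test_square_well_doubles_flat_value(self):
        kbt = KB * 300
        r = np.linspace(0, 10, 500)
        prof = np.column_stack([r, np.full_like(r, -kbt * np.log(2))])
        flat = pmf_binding_constant(np.column_stack([r, np.zeros_like(r)]), 10.0)
        with pytest.warns(RuntimeWarning):
            K = pmf_binding_constant(prof, 10.0)
        assert K == pytest.approx(2 * flat, rel=1e-12)

    def test_profile_must_cover_range(self):
        prof = np.column_stack([np.linspace(2, 10, 20), np.zeros(20)])
        with pytest.raises(ValueError):
            pmf_binding_constant(prof, 10.0)


class TestBootstrap:
    def test_clt_scaling_on_iid_means(self):
        rng = np.random.default_rng(6)
        sigma = 2.0
        trajs = [rng.normal(0, sigma, 100) for _ in range(50)]

        def grand_mean(sample):
            return float(np.mean(np.concatenate(sample)))

        _, sd, failures = bootstrap_errors(trajs, grand_mean, n_boot=200, seed=1)
        expected = sigma / np.sqrt(50 * 100)
        assert failures == 0
        assert abs(sd - expected) / expected < 0.3

    def test_constant_estimator_zero_spread(self):
        trajs = [np.zeros(5) for _ in range(4)]
        mean, sd, _ = bootstrap_errors(trajs, lambda s: 3.14, n_boot=10, seed=0)
        assert mean == pytest.approx(3.14)
        assert sd == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_errors([np.zeros(3), np.zeros(3)], lambda s: 0.0, n_boot=1)

    def test_failures_reported(self):
        trajs = [np.arange(3), np.arange(3), np.arange(3)]
        calls = {"n": 0}

        def flaky(sample):
            calls["n"] += 1
            if calls["n"] % 2 == 0:
                raise RuntimeError("boom")
            return 1.0

        _, _, failures = bootstrap_errors(trajs, flaky, n_boot=10, seed=2)
        assert failures == 5


def test_pcca_bound_set_selects_short_com_block():
    """Two-state PCCA on a two-basin chain labels the short-COM basin bound."""
    from gomsm.synthetic import birth_death_reference
    from gomsm.workflow import bound_set_from_pcca

    ref = birth_death_reference([0.0, 0.3, 4.5, 0.4, 0.1])
    m = _model_from_T(ref.T, lag_time=1.0)
    com = np.array([6.0, 8.0, 15.0, 30.0, 40.0])
    bound = bound_set_from_pcca(m, com)
    assert set(bound.tolist()) <= {0, 1, 2}
    assert 0 in bound and 1 in bound
    assert 4 not in bound
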