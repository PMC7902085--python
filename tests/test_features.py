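"""Featurization, TICA and discretization checks."""

import numpy as np
import pytest

from gomsm.features import (
    FeatureSeries,
    elbow_choose_k,
    geometry_features,
    kmeans_cluster,
    long_lived_contacts,
    rmsd_min,
    tica_fit,
    tica_transform,
)
from gomsm.simulate import LangevinParams, RunResult


def _run_from_frames(frames, chain_sizes=(1, 1), interval_ns=0.01, masses=None):
    frames = np.asarray(frames, dtype=float)
    nA, nB = chain_sizes
    chain_ids = np.array([0] * nA + [1] * nB)
    if masses is None:
        masses = np.ones(nA + nB)
    params = LangevinParams(timestep=interval_ns * 1e6, n_steps=max(1, len(frames) - 1),
                            save_stride=1, seed=0)
    return RunResult(
        frames=frames,
        frame_times=np.arange(len(frames)) * interval_ns,
        params=params,
        chain_ids=chain_ids,
        masses=np.asarray(masses, dtype=float),
    )


class TestGeometryFeatures:
    def test_com_distance_3_4_5(self):
        run = _run_from_frames([[[0, 0, 0], [3, 4, 0]]])
        fs = geometry_features(run, "com_distance")
        assert fs.values[0, 0] == pytest.approx(5.0)

    def test_inverse_sq_com(self):
        run = _run_from_frames([[[0, 0, 0], [3, 4, 0]]])
        fs = geometry_features(run, "inverse_sq_com")
        assert fs.values[0, 0] == pytest.approx(0.04)

    def test_mass_weighted_com(self):
        run = _run_from_frames(
            [[[0, 0, 0], [2, 0, 0], [10, 0, 0]]], chain_sizes=(2, 1),
            masses=[1.0, 1.0, 5.0],
        )
        fs = geometry_features(run, "com_distance")
        assert fs.values[0, 0] == pytest.approx(9.0)

    def test_pair_distances_and_invalid_pair(self):
        run = _run_from_frames([[[0, 0, 0], [0, 0, 7]]])
        fs = geometry_features(run, "pair_distances", pairs=[(0, 0)])
        assert fs.values[0, 0] == pytest.approx(7.0)
        with pytest.raises(IndexError):
            geometry_features(run, "pair_distances", pairs=[(0, 5)])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(-5, 5, (10, 2, 3))
        run = _run_from_frames(frames)
        fs = geometry_features(run, "com_distance").values
        perm = rng.permutation(10)
        fs_perm = geometry_features(_run_from_frames(frames[perm]), "com_distance").values
        assert np.allclose(fs[perm], fs_perm)


class TestRmsdMin:
    def test_identity_and_rigid_rotation(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        ref = rng.uniform(-5, 5, (6, 3))
        R = Rotation.random(random_state=2).as_matrix()
        rotated = (ref - ref.mean(axis=0)) @ R.T + np.array([3, 1, -2])
        run = _run_from_frames(np.stack([ref, rotated]), chain_sizes=(3, 3))
        fs = rmsd_min(run, ref)
        assert fs.values[0, 0] == pytest.approx(0.0, abs=1e-8)
        assert fs.values[1, 0] == pytest.approx(0.0, abs=1e-8)

    def test_two_bead_stretch_closed_form(self):
        d, delta = 4.0, 0.6
        ref = np.array([[0, 0, 0], [d, 0, 0.0]])
        frame = np.array([[0, 0, 0], [d + delta, 0, 0.0]])
        run = _run_from_frames(frame[None])
        assert rmsd_min(run, ref).values[0, 0] == pytest.approx(delta / 2)

    def test_mismatched_counts(self):
        run = _run_from_frames([[[0, 0, 0], [1, 0, 0]]])
        with pytest.raises(ValueError):
            rmsd_min(run, np.zeros((3, 3)))


class TestLongLivedContacts:
    def _run_with_distance(self, dists, interval_ns=0.01):
        frames = np.zeros((len(dists), 2, 3))
        frames[:, 1, 0] = dists
        return _run_from_frames(frames, interval_ns=interval_ns)

    def test_persistent_pair_kept(self):
        run = self._run_with_distance([5.0] * 200, interval_ns=0.01)  # 2 ns run
        assert long_lived_contacts([run], 12.0, 1.0) == [(0, 0)]

    def test_single_frame_blip_dropped(self):
        dists = [20.0] * 100
        dists[50] = 5.0
        run = self._run_with_distance(dists, interval_ns=0.01)
        assert long_lived_contacts([run], 12.0, 1.0) == []

    def test_alternating_pair_dropped(self):
        dists = [5.0, 20.0] * 100
        run = self._run_with_distance(dists, interval_ns=0.01)
        assert long_lived_contacts([run], 12.0, 1.0) == []

    def test_boundary_distance_counts_as_unbound(self):
        run = self._run_with_distance([12.0] * 200, interval_ns=0.01)
        assert long_lived_contacts([run], 12.0, 1.0) == []

    def test_monotone_in_cutoff_and_lifetime(self):
        rng = np.random.default_rng(4)
        dists = 10 + 5 * np.sin(np.arange(300) / 7) + rng.normal(0, 1, 300)
        run = self._run_with_distance(np.abs(dists), interval_ns=0.01)
        base = set(long_lived_contacts([run], 12.0, 0.5))
        assert base <= set(long_lived_contacts([run], 14.0, 0.5))
        assert base <= set(long_lived_contacts([run], 12.0, 0.2))

    def test_unresolvable_lifetime_rejected(self):
        run = self._run_with_distance([5.0] * 10, interval_ns=0.5)
        with pytest.raises(ValueError):
            long_lived_contacts([run], 12.0, 0.1)


def _ar1(n, phi, seed, sigma=1.0):
    rng = np.random.default_rng(seed)
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(0, sigma, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


class TestTICA:
    def test_ar1_eigenvalue_matches_autocorrelation(self):
        x = _ar1(100_000, 0.9, seed=0)
        fs = FeatureSeries(x[:, None], ["x"], 0.01)
        model = tica_fit(fs, lag=1)
        assert model.eigenvalues[0] == pytest.approx(0.9, abs=0.02)

    def test_two_independent_ar1_dims(self):
        x = _ar1(200_000, 0.9, seed=1)
        y = _ar1(200_000, 0.5, seed=2)
        fs = FeatureSeries(np.column_stack([x, y]), ["x", "y"], 0.01)
        model = tica_fit(fs, lag=1)
        assert model.eigenvalues[0] == pytest.approx(0.9, abs=0.02)
        assert model.eigenvalues[1] == pytest.approx(0.5, abs=0.02)
        # eigenvectors axis-aligned up to sign
        u = np.abs(model.eigenvectors / np.linalg.norm(model.eigenvectors, axis=0))
        assert u[0, 0] > 0.99 and u[1, 1] > 0.99

    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(3)
        n = 50_000
        fs = FeatureSeries(rng.normal(size=(n, 2)), ["a", "b"], 0.01)
        model = tica_fit(fs, lag=1)
        assert np.all(np.abs(model.eigenvalues) < 3 / np.sqrt(n))

    def test_eigenvalues_within_unit_interval_on_reversible_data(self):
        x = _ar1(50_000, 0.8, seed=5)
        y = 0.5 * x + _ar1(50_000, 0.3, seed=6)
        fs = FeatureSeries(np.column_stack([x, y]), ["x", "y"], 0.01)
        model = tica_fit(fs, lag=2)
        n_eff = 50_000
        assert np.all(model.eigenvalues < 1 + 3 / np.sqrt(n_eff))
        assert np.all(model.eigenvalues > -1 - 3 / np.sqrt(n_eff))

    def test_transform_identity_and_mean(self):
        x = _ar1(1000, 0.7, seed=7)
        fs = FeatureSeries(x[:, None], ["x"], 0.01)
        model = tica_fit(fs, lag=1)
        z = tica_transform(model, fs, 1)
        # proportional to mean-free input
        corr = np.corrcoef(z.values[:, 0], x - x.mean())[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)
        zm = tica_transform(model, FeatureSeries(model.mean[None, :], ["x"], 0.01), 1)
        assert np.allclose(zm.values, 0.0)

    def test_ic1_beats_random_projections(self):
        rng = np.random.default_rng(8)
        x = _ar1(20_000, 0.9, seed=9)
        noise = rng.normal(size=(20_000, 3))
        X = np.column_stack([x + noise[:, 0] * 0.1, noise[:, 1], noise[:, 2]])
        fs = FeatureSeries(X, ["a", "b", "c"], 0.01)
        model = tica_fit(fs, lag=1)
        z = tica_transform(model, fs, 1).values[:, 0]

        def lag_autocorr(v):
            v = v - v.mean()
            return np.dot(v[:-1], v[1:]) / np.dot(v, v)

        best_random = max(
            lag_autocorr(X @ (lambda u: u / np.linalg.norm(u))(rng.normal(size=3)))
            for _ in range(100)
        )
        assert lag_autocorr(z) >= best_random - 1e-9

    def test_series_shorter_than_lag_rejected(self):
        fs = FeatureSeries(np.zeros((5, 1)) + np.arange(5)[:, None], ["x"], 0.01)
        with pytest.raises(ValueError):
            tica_fit(fs, lag=5)


class TestKMeansAndElbow:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 0.3, (200, 2))
        b = rng.normal(8, 0.3, (200, 2))
        X = np.vstack([a, b])
        labels_true = np.array([0] * 200 + [1] * 200)
        disc = kmeans_cluster(X, 2, seed=0)
        # map cluster ids to blob ids
        agree = max(
            np.mean(disc.assignments == labels_true),
            np.mean(disc.assignments == 1 - labels_true),
        )
        assert agree == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        X = np.arange(6, dtype=float).reshape(6, 1) * 3
        disc = kmeans_cluster(X, 6, seed=0)
        assert disc.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_cluster(np.zeros((3, 1)), 4)

    def test_elbow_finds_constructed_knee(self):
        ks = range(1, 11)
        inertia = {k: (100 - 18 * k if k <= 5 else 10 - 0.5 * (k - 5)) for k in ks}
        assert elbow_choose_k(inertia) == 5

    def test_elbow_degenerate_linear_curve(self):
        inertia = {k: 100 - 10 * k for k in range(1, 6)}
        with pytest.warns(RuntimeWarning):
            assert elbow_choose_k(inertia) == 2

    def test_elbow_needs_three_points(self):
        with pytest.raises(ValueError):
            elbow_choose_k({1: 10.0, 2: 5.0})


def test_feature_series_text_round_trip(tmp_path):
    rng = np.random.default_rng(11)
    fs = FeatureSeries(rng.normal(size=(20, 3)), ["a", "b", "c"], 0.25)
    path = tmp_path / "feats.tsv"
    fs.to_text(path)
    back = FeatureSeries.from_text(path)
    assert back.names == fs.names
    assert back.frame_interval == fs.frame_interval
    assert np.allclose(back.values, fs.values)
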