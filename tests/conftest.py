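"""Shared fixtures: one toy-complex simulation campaign reused by the
whole-workflow tests, built once per session."""

import numpy as np
import pytest

from gomsm.workflow import WorkflowConfig, build_dataset, analyze


#: study configuration of the desk-scale toy campaign
TOY_SEED = 1


def toy_config(recipe="tram_1d", **overrides):
    base = dict(recipe=recipe, seed=TOY_SEED, n_boot=10, tram_tol=1e-6)
    base.update(overrides)
    return WorkflowConfig(**base)


@pytest.fixture(scope="session")
def toy_dataset():
    """Unbiased + umbrella campaigns on the default toy complex."""
    return build_dataset(toy_config())


@pytest.fixture(scope="session")
def recipe_reports(toy_dataset):
    """All four model recipes analyzed on the shared campaign."""
    return {
        recipe: analyze(toy_dataset, toy_config(recipe))
        for recipe in ("msm_6d", "tram_6d", "tram_1d", "tram_1d_inv")
    }


@pytest.fixture(scope="session")
def reference_runs(toy_dataset):
    """Extra long unbiased runs, used only to converge the reference
    free-energy profile that scaled-down estimates are compared against."""
    from gomsm.simulate import LangevinParams, run_langevin

    cfg = toy_config()
    runs = []
    for r in range(4):
        p = LangevinParams(
            temperature=cfg.temperature, friction=cfg.friction,
            timestep=cfg.timestep, n_steps=250_000,
            save_stride=cfg.save_stride, seed=cfg.seed * 10_000 + 500 + r,
        )
        runs.append(run_langevin(toy_dataset.cplx, p))
    return runs


@pytest.fixture(scope="session")
def com_discretization(toy_dataset):
    """COM-distance k-means microstates over all frames (unbiased+biased),
    with per-run discrete trajectories and window-bias matrices."""
    from gomsm.features import geometry_features, kmeans_cluster
    from gomsm.msm import DiscreteTrajectory
    from gomsm.simulate import bias_energy_matrix

    cfg = toy_config()
    runs = list(toy_dataset.unbiased) + list(toy_dataset.biased)
    feats = [geometry_features(r, "com_distance") for r in runs]
    X = np.vstack([f.values for f in feats])
    disc = kmeans_cluster(X, cfg.n_microstates, seed=cfg.seed)
    interval = runs[0].frame_interval
    dtrajs, ofs = [], 0
    for f in feats:
        dtrajs.append(DiscreteTrajectory(disc.assignments[ofs:ofs + f.n_frames], interval))
        ofs += f.n_frames
    state_com = np.array([
        X[disc.assignments == i, 0].mean() if np.any(disc.assignments == i) else np.nan
        for i in range(disc.k)
    ])
    n_unb = len(toy_dataset.unbiased)
    K = len(toy_dataset.windows) + 1
    bias_unb = []
    for run, d in zip(toy_dataset.unbiased, dtrajs[:n_unb]):
        b = np.zeros((len(d), K))
        b[:, 1:] = bias_energy_matrix(
            run.frames, run.chain_ids, run.masses, toy_dataset.windows, cfg.temperature
        )
        bias_unb.append(b)
    bias_us = []
    for run, d in zip(toy_dataset.biased, dtrajs[n_unb:]):
        b = np.zeros((len(d), K))
        b[:, 1:] = run.bias_energies
        bias_us.append(b)
    return {
        "disc": disc,
        "dtrajs_unb": dtrajs[:n_unb],
        "dtrajs_us": dtrajs[n_unb:],
        "bias_unb": bias_unb,
        "bias_us": bias_us,
        "state_com": state_com,
        "lag": max(1, int(round(cfg.lag_ns / interval))),
        "interval": interval,
        "config": cfg,
    }
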