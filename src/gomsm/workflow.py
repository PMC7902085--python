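"""End-to-end model recipes: simulate -> featurize -> discretize -> estimate.

Four recipes mirror the standard study designs for two-body association:

* ``msm_6d``   — TICA components of long-lived inter-chain pair distances,
  plus the COM distance and the minimum RMSD to the bound pose, clustered
  and estimated as a reversible MSM from unbiased runs only.
* ``tram_6d``  — the same feature space, estimated with TRAM from unbiased
  runs plus umbrella windows.
* ``tram_1d``  — COM distance only, TRAM on unbiased + umbrella data.
* ``tram_1d_inv`` — squared inverse COM distance, TRAM likewise.

Each recipe reports the equilibrium constant K_eq, the binding free energy,
and (where the unbiased transition model is connected) association and
dissociation rates, with bootstrap errors over unbiased trajectories.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .constants import KB
from .features import (
    FeatureSeries,
    geometry_features,
    kmeans_cluster,
    long_lived_contacts,
    rmsd_min,
    tica_fit,
    tica_transform,
)
from .model import CGComplex
from .msm import (
    DiscreteTrajectory,
    MarkovModel,
    binding_observables,
    bootstrap_errors,
    count_transitions,
    estimate_transition_matrix,
    _stationary_from_T,
)
from .simulate import (
    LangevinParams,
    RunResult,
    WindowSet,
    bias_energy_matrix,
    make_window_grid,
    run_langevin,
    run_umbrella_set,
)
from .synthetic import ToyComplexSpec, make_toy_complex
from .tram import EnsembleData, estimate_tram, free_energy_profile

RECIPES = ("msm_6d", "tram_6d", "tram_1d", "tram_1d_inv")


@dataclass
class WorkflowConfig:
    """All knobs of a toy-complex workflow, with defaults sized for minutes
    of desk-scale simulation rather than the production campaign."""

    recipe: str = "tram_1d"
    seed: int = 0
    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 20.0  # fs; soft CG potentials tolerate long steps
    # unbiased campaign
    n_runs: int = 6
    n_steps: int = 120_000
    save_stride: int = 25  # 0.5 ps between saved frames
    # umbrella campaign: 1 A spacing at 1 kcal/mol/A^2, as in the
    # production protocol, scaled to the toy cavity
    window_start: float = 5.0
    window_stop: float = 24.0
    window_spacing: float = 1.0
    window_spring_k: float = 1.0
    us_n_steps: int = 20_000
    # featurization / discretization
    contact_cutoff: float = 12.0
    contact_min_lifetime: float = 0.01  # ns, toy scale
    tica_lag: int = 5
    n_tica_components: int = 2
    n_microstates: int = 30
    # estimation
    lag_ns: float = 0.02
    reversible: bool = True
    bound_mode: str = "rcut"  # or "pcca"
    r_cut: float = 12.0
    n_boot: int = 10
    tram_tol: float = 1e-8
    tram_max_iter: int = 50_000
    # toy system
    toy_nA: int = 8
    toy_nB: int = 6
    toy_n_contacts: int = 3
    toy_epsilon: float = 1.25
    toy_r_cavity: float = 25.0

    def __post_init__(self):
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; choose from {RECIPES}")

    @classmethod
    def from_dict(cls, d: dict) -> "WorkflowConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Dataset:
    """Shared simulation inputs for one or more recipes."""

    cplx: CGComplex
    reference: np.ndarray
    unbiased: list[RunResult]
    windows: WindowSet
    biased: list[RunResult]


def build_dataset(config: WorkflowConfig, cplx: CGComplex | None = None,
                  reference: np.ndarray | None = None) -> Dataset:
    """Run the unbiased and umbrella campaigns for a (toy) complex."""
    if cplx is None:
        cplx, reference = make_toy_complex(ToyComplexSpec(
            nA=config.toy_nA, nB=config.toy_nB, n_contacts=config.toy_n_contacts,
            seed=config.seed, epsilon=config.toy_epsilon, r_cavity=config.toy_r_cavity,
        ))
    unbiased = []
    for r in range(config.n_runs):
        p = LangevinParams(
            temperature=config.temperature, friction=config.friction,
            timestep=config.timestep, n_steps=config.n_steps,
            save_stride=config.save_stride, seed=config.seed * 10_000 + r,
        )
        unbiased.append(run_langevin(cplx, p))
    windows = make_window_grid(
        config.window_start, config.window_stop, config.window_spacing,
        config.window_spring_k,
    )
    us_params = LangevinParams(
        temperature=config.temperature, friction=config.friction,
        timestep=config.timestep, n_steps=config.us_n_steps,
        save_stride=config.save_stride, seed=config.seed * 10_000 + 1000,
    )
    biased = run_umbrella_set(cplx, windows, us_params)
    return Dataset(cplx=cplx, reference=reference, unbiased=unbiased,
                   windows=windows, biased=biased)


def _featurize(runs: list[RunResult], recipe: str, config: WorkflowConfig,
               reference: np.ndarray, contact_pairs, tica_model=None):
    """Per-run feature matrices for the recipe; returns (series list, tica)."""
    if recipe in ("tram_1d", "msm_1d"):
        return [geometry_features(r, "com_distance") for r in runs], None
    if recipe == "tram_1d_inv":
        return [geometry_features(r, "inverse_sq_com") for r in runs], None
    # 6D: TICA(pair distances) + RMSD + COM
    pair_series = [geometry_features(r, "pair_distances", pairs=contact_pairs) for r in runs]
    if tica_model is None:
        tica_model = tica_fit(pair_series, lag=config.tica_lag)
    out = []
    for r, ps in zip(runs, pair_series):
        ics = tica_transform(tica_model, ps, config.n_tica_components)
        com = geometry_features(r, "com_distance")
        rms = rmsd_min(r, reference)
        vals = np.column_stack([ics.values, rms.values, com.values])
        names = ics.names + rms.names + com.names
        out.append(FeatureSeries(vals, names, r.frame_interval))
    return out, tica_model


def _com_series(runs):
    return [geometry_features(r, "com_distance") for r in runs]


@dataclass
class RecipeReport:
    recipe: str
    K_eq: float
    K_eq_err: float | None
    dG_b: float
    P_bound: float
    k_on: float | None
    k_off: float | None
    n_microstates: int
    state_com: np.ndarray
    pi: np.ndarray
    profile_bins: np.ndarray
    profile_W: np.ndarray
    model: object
    bound_states: np.ndarray
    bootstrap_failures: int = 0


def analyze(dataset: Dataset, config: WorkflowConfig) -> RecipeReport:
    """Run one recipe's featurize/discretize/estimate/observe pipeline."""
    recipe = config.recipe
    use_us = recipe.startswith("tram")
    runs = list(dataset.unbiased) + (list(dataset.biased) if use_us else [])

    contact_pairs = None
    if recipe.endswith("6d"):
        contact_pairs = long_lived_contacts(
            dataset.unbiased, config.contact_cutoff, config.contact_min_lifetime
        )
        if not contact_pairs:
            raise RuntimeError("no long-lived contacts found; cannot build 6D features")

    feats, _ = _featurize(runs, recipe, config, dataset.reference, contact_pairs)
    X = np.vstack([f.values for f in feats])
    disc = kmeans_cluster(X, config.n_microstates, seed=config.seed)

    frame_interval = runs[0].frame_interval
    lag = max(1, int(round(config.lag_ns / frame_interval)))
    dtrajs = []
    ofs = 0
    for f in feats:
        n = f.n_frames
        dtrajs.append(DiscreteTrajectory(disc.assignments[ofs:ofs + n], frame_interval))
        ofs += n
    n_unb = len(dataset.unbiased)
    dtrajs_unb = dtrajs[:n_unb]
    dtrajs_us = dtrajs[n_unb:]

    # average COM distance per microstate (over all frames used)
    com_all = np.concatenate([s.values[:, 0] for s in _com_series(runs)])
    state_com = np.full(disc.k, np.nan)
    for i in range(disc.k):
        sel = disc.assignments == i
        if sel.any():
            state_com[i] = com_all[sel].mean()

    temperature = config.temperature

    # per-run window-bias matrices for the unbiased data (column 0 = zero)
    K = len(dataset.windows) + 1
    items = []
    for d, run in zip(dtrajs_unb, dataset.unbiased):
        b = np.zeros((len(d), K))
        b[:, 1:] = bias_energy_matrix(
            run.frames, run.chain_ids, run.masses, dataset.windows, temperature
        )
        items.append((d, b))

    def estimate(subset):
        if use_us:
            ens = [EnsembleData(dtrajs=[d for d, _ in subset],
                                bias=np.vstack([b for _, b in subset]),
                                ensemble_id=0)]
            for w, (d, run) in enumerate(zip(dtrajs_us, dataset.biased)):
                bw = np.zeros((len(d), K))
                bw[:, 1:] = run.bias_energies
                ens.append(EnsembleData(dtrajs=[d], bias=bw, ensemble_id=w + 1))
            tm = estimate_tram(ens, lag, tol=config.tram_tol,
                               max_iter=config.tram_max_iter)
            return tm.unbiased_pi, tm.active_set, tm
        cm = count_transitions([d for d, _ in subset], lag)
        mm = estimate_transition_matrix(cm, reversible=config.reversible)
        return mm.pi, mm.active_set, mm

    r_cavity = dataset.cplx.confinement.r_cavity

    def keq_of(subset):
        pi, active, mdl = estimate(subset)
        split_model = (_as_markov_model(mdl, lag * frame_interval)
                       if config.bound_mode == "pcca" else None)
        return _keq_details(pi, state_com[active], config, r_cavity,
                            model=split_model)[0]

    pi, active, model = estimate(items)
    com_active = state_com[active]
    mm_for_split = None
    if config.bound_mode == "pcca":
        mm_for_split = _as_markov_model(model, lag * frame_interval)
    K_eq, P_b, bound_local = _keq_details(pi, com_active, config, r_cavity,
                                          model=mm_for_split)
    kbt = KB * temperature
    dG = -kbt * np.log(P_b / (1.0 - P_b))

    K_err = None
    failures = 0
    if config.n_boot >= 2 and n_unb >= 2:
        _, K_err, failures = bootstrap_errors(
            items, keq_of, n_boot=config.n_boot, seed=config.seed + 7
        )

    k_on = k_off = None
    try:
        mm = _as_markov_model(model, lag * frame_interval)
        amap = {s: i for i, s in enumerate(active)}
        bound_m = np.array([amap[s] for s in active[bound_local]])
        obs = binding_observables(
            mm, bound_m, r_cavity=dataset.cplx.confinement.r_cavity,
            r_cut=config.r_cut, temperature=temperature,
        )
        k_on, k_off = obs.k_on, obs.k_off
    except Exception:
        pass

    # free-energy profile along COM bins (1 A width)
    edges = np.arange(0.0, np.nanmax(com_active) + 2.0, 1.0)
    bin_map = np.clip(np.digitize(com_active, edges) - 1, 0, len(edges) - 1)
    bins, W = free_energy_profile(pi, bin_map, temperature)
    centers = edges[bins] + 0.5

    return RecipeReport(
        recipe=recipe, K_eq=K_eq, K_eq_err=K_err, dG_b=float(dG), P_bound=P_b,
        k_on=k_on, k_off=k_off, n_microstates=disc.k, state_com=state_com,
        pi=pi, profile_bins=centers, profile_W=W, model=model,
        bound_states=active[bound_local], bootstrap_failures=failures,
    )


def run_workflow(config: WorkflowConfig, dataset: Dataset | None = None) -> RecipeReport:
    """Build (or reuse) the dataset and run the configured recipe."""
    if dataset is None:
        dataset = build_dataset(config)
    return analyze(dataset, config)


def bound_set_from_pcca(model: MarkovModel, com_active) -> np.ndarray:
    """Two-state PCCA split; the metastable set with the smaller
    pi-weighted average COM distance is the bound state."""
    from .msm import pcca_assign

    labels = pcca_assign(model, 2).crisp_labels
    com_active = np.asarray(com_active)
    means = []
    for m in (0, 1):
        sel = labels == m
        if not sel.any():
            raise RuntimeError("degenerate two-state PCCA split")
        w = model.pi[sel]
        means.append(float(np.average(com_active[sel], weights=w)))
    bound_label = int(np.argmin(means))
    return np.where(labels == bound_label)[0]


def _keq_details(pi, com_active, config, r_cavity, model=None):
    from .msm import bulk_volume

    if config.bound_mode == "pcca":
        if model is None:
            raise RuntimeError("PCCA bound-set path needs a Markov model")
        bound = bound_set_from_pcca(model, com_active)
    else:
        bound = np.where(com_active <= config.r_cut)[0]
    if len(bound) == 0 or len(bound) == len(pi):
        raise RuntimeError("bound/unbound split degenerate")
    P_b = float(pi[bound].sum())
    V = bulk_volume(r_cavity, config.r_cut)
    return (P_b / (1.0 - P_b)) * V, P_b, bound


def _as_markov_model(model, lag_time) -> MarkovModel:
    """View an estimate as a MarkovModel on its active set (TRAM: the
    unbiased ensemble's transition matrix)."""
    if isinstance(model, MarkovModel):
        return model
    T = model.transition_matrices[0]
    from scipy.sparse.csgraph import connected_components
    import scipy.sparse as sp

    ncomp, _ = connected_components(sp.csr_matrix(T > 1e-12), directed=True, connection="strong")
    if ncomp > 1:
        raise ValueError("unbiased TRAM transition matrix is reducible")
    pi = _stationary_from_T(T)
    evals = np.sort(np.linalg.eigvals(T).real)[::-1]
    return MarkovModel(T=T, lag_time=lag_time, pi=pi, eigenvalues=evals,
                       active_set=model.active_set, reversible=True)
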