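"""Langevin dynamics and umbrella-sampling campaigns.

Propagation uses the BAOAB splitting of underdamped Langevin dynamics,
which samples configurational averages accurately at the soft force
constants of the coarse-grained model even at multi-femtosecond steps.
Umbrella campaigns run one biased trajectory per window of a uniform grid
of harmonic windows on the chain-chain COM distance and record, for every
saved frame, the reduced bias energy that frame would feel in *every*
window — the input multi-ensemble bias matrix for TRAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ACCEL_UNIT, KB
from .model import CGComplex, UmbrellaBias, com_distance, forces

__all__ = [
    "LangevinParams",
    "WindowSet",
    "RunResult",
    "run_langevin",
    "make_window_grid",
    "run_umbrella_set",
    "randomized_dissociated_pose",
]


@dataclass(frozen=True)
class LangevinParams:
    """Integration parameters (temperature K, friction ps^-1, timestep fs)."""

    temperature: float = 300.0
    friction: float = 1.0
    timestep: float = 1.0
    n_steps: int = 1000
    save_stride: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 1 or self.save_stride < 1:
            raise ValueError("n_steps and save_stride must be >= 1")


@dataclass(frozen=True)
class WindowSet:
    """Uniformly spaced umbrella-window centers along the COM distance."""

    centers: tuple[float, ...]
    spring_k: float = 1.0

    def __post_init__(self):
        c = np.asarray(self.centers)
        if c.size == 0:
            raise ValueError("window set must contain at least one center")
        if c.size > 1:
            d = np.diff(c)
            if np.any(d <= 0):
                raise ValueError("centers must be strictly increasing")
            if not np.allclose(d, d[0]):
                raise ValueError("centers must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.centers)

    def biases(self) -> list[UmbrellaBias]:
        return [UmbrellaBias(c, self.spring_k) for c in self.centers]


@dataclass
class RunResult:
    """A saved trajectory with optional per-window bias energies.

    ``frames`` has shape (n_frames, n_beads, 3) in Angstrom, ``frame_times``
    in ns.  ``bias_energies`` (n_frames, n_windows), if present, holds the
    reduced bias u_k(x)/k_BT of each frame in every umbrella window.
    ``chain_ids`` (0 for chain A, 1 for chain B) and ``masses`` are carried
    along so featurization needs no access to the original complex.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    params: LangevinParams
    chain_ids: np.ndarray
    masses: np.ndarray
    window: UmbrellaBias | None = None
    bias_energies: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_interval(self) -> float:
        """Time between saved frames, ns."""
        return self.params.timestep * self.params.save_stride * 1e-6


def run_langevin(
    cplx: CGComplex,
    params: LangevinParams,
    start: np.ndarray | None = None,
    bias: UmbrellaBias | None = None,
) -> RunResult:
    """Propagate BAOAB Langevin dynamics; bit-reproducible per seed."""
    pos = np.array(cplx.reference if start is None else start, dtype=float)
    if pos.shape != (cplx.n_beads, 3):
        raise ValueError("start positions have wrong shape")

    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    kbt = KB * params.temperature
    m = cplx.masses[:, None]
    # thermal velocity scale, A/fs
    sigma_v = np.sqrt(kbt * ACCEL_UNIT / m)
    gamma_fs = params.friction * 1e-3
    c1 = np.exp(-gamma_fs * dt)
    c2 = np.sqrt(1.0 - c1 * c1)

    vel = sigma_v * rng.standard_normal(pos.shape)
    f = forces(cplx, pos, bias)

    n_saved = params.n_steps // params.save_stride + 1
    frames = np.empty((n_saved, cplx.n_beads, 3))
    frames[0] = pos
    isave = 1
    for step in range(1, params.n_steps + 1):
        vel += 0.5 * dt * ACCEL_UNIT * f / m
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * sigma_v * rng.standard_normal(pos.shape)
        pos += 0.5 * dt * vel
        if not np.isfinite(pos).all():
            raise FloatingPointError(f"non-finite coordinates at step {step} (integrator blow-up)")
        f = forces(cplx, pos, bias)
        vel += 0.5 * dt * ACCEL_UNIT * f / m
        if step % params.save_stride == 0:
            frames[isave] = pos
            isave += 1

    times = np.arange(n_saved) * params.save_stride * dt * 1e-6  # ns
    return RunResult(
        frames=frames,
        frame_times=times,
        params=params,
        chain_ids=cplx.chain_ids.copy(),
        masses=cplx.masses.copy(),
        window=bias,
    )


def make_window_grid(start: float, stop: float, spacing: float, spring_k: float = 1.0) -> WindowSet:
    """Inclusive uniform grid of umbrella windows: start, start+spacing, ..., stop."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if stop < start:
        raise ValueError("stop must be >= start")
    n = int(round((stop - start) / spacing)) + 1
    centers = start + spacing * np.arange(n)
    centers = tuple(float(c) for c in centers if c <= stop + 1e-9)
    return WindowSet(centers=centers, spring_k=spring_k)


def bias_energy_matrix(frames, chain_ids, masses, windows: WindowSet, temperature: float) -> np.ndarray:
    """Reduced bias energies u_k/k_BT of each frame in every window."""
    kbt = KB * temperature
    d = _com_distances(np.asarray(frames), chain_ids, masses)
    centers = np.asarray(windows.centers)
    return 0.5 * windows.spring_k * (d[:, None] - centers[None, :]) ** 2 / kbt


def _com_distances(frames: np.ndarray, chain_ids: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Per-frame mass-weighted chain-chain COM distance, vectorized."""
    a = chain_ids == 0
    b = chain_ids == 1
    wa = masses[a] / masses[a].sum()
    wb = masses[b] / masses[b].sum()
    com_a = np.einsum("fij,i->fj", frames[:, a, :], wa)
    com_b = np.einsum("fij,i->fj", frames[:, b, :], wb)
    return np.linalg.norm(com_b - com_a, axis=1)


def randomized_dissociated_pose(
    cplx: CGComplex, distance: float, seed: int
) -> np.ndarray:
    """Chain A at its reference pose; chain B rigidly rotated at random and
    placed with its COM at ``distance`` along a random direction.

    Randomizing the separation direction and the mutual orientation matters
    for umbrella windows: runs too short to diffuse around the spherical
    shell would otherwise all inherit the bound pose's interface alignment,
    biasing mid-range windows toward residual attraction.  Orientations
    that would drop a Go contact pair far inside its well wall are
    resampled.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    pos = cplx.reference.copy()
    com_A = np.average(pos[cplx.idx_A], axis=0, weights=cplx.mass_A)
    B0 = pos[cplx.idx_B]
    com_B = np.average(B0, axis=0, weights=cplx.mass_B)
    for _ in range(100):
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        R = Rotation.random(random_state=rng).as_matrix()
        B = (B0 - com_B) @ R.T + com_A + distance * u
        trial = pos.copy()
        trial[cplx.idx_B] = B
        ok = True
        for c, gi, gj in zip(cplx.contacts, cplx._c_i, cplx._c_j):
            if np.linalg.norm(trial[gi] - trial[gj]) < 0.9 * c.r_min:
                ok = False
                break
        if ok:
            return trial
    return pos  # keep the reference pose if no clash-free placement found


def run_umbrella_set(
    cplx: CGComplex,
    windows: WindowSet,
    params: LangevinParams,
    start: np.ndarray | None = None,
    start_mode: str = "randomized",
) -> list[RunResult]:
    """One biased run per window, deterministically seeded from the base seed.

    By default each window starts from a randomized pose with the chain-B
    COM placed at the window centre (``start_mode="randomized"``); pass
    ``start_mode="reference"`` or an explicit ``start`` to override.  Every
    run's frames are evaluated in *all* windows' bias potentials and the
    reduced energies (k_BT units) stored on the run — the TRAM input.
    """
    if len(windows) == 0:
        raise ValueError("window set is empty")
    if start_mode not in ("randomized", "reference"):
        raise ValueError("start_mode must be 'randomized' or 'reference'")
    results = []
    for w, bias in enumerate(windows.biases()):
        p = LangevinParams(
            temperature=params.temperature,
            friction=params.friction,
            timestep=params.timestep,
            n_steps=params.n_steps,
            save_stride=params.save_stride,
            seed=params.seed + w,
        )
        if start is not None:
            w_start = start
        elif start_mode == "randomized":
            w_start = randomized_dissociated_pose(cplx, bias.center, seed=p.seed + 90_001)
        else:
            w_start = None
        run = run_langevin(cplx, p, start=w_start, bias=bias)
        run.bias_energies = bias_energy_matrix(
            run.frames, run.chain_ids, run.masses, windows, params.temperature
        )
        results.append(run)
    return results
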