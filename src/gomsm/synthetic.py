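"""Synthetic fixtures and analytic oracles.

Provides (i) toy two-chain bead complexes whose bound pose is by
construction the joint minimum of their Go contacts, small enough that full
association/dissociation statistics are reachable in seconds to minutes of
Langevin simulation; (ii) discrete Markov chain samplers; (iii) birth-death
reference chains with closed-form Boltzmann stationary distributions and
first-step-recursion MFPT tables, used as exact oracles for the MSM and TRAM
estimators; and (iv) a two-basin jump-diffusion COM-distance trace with a
known separatrix for validating the bound-state cutoff scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CGComplex, ConfinementSphere, RestraintSpec, build_complex

__all__ = [
    "ToyComplexSpec",
    "BirthDeathReference",
    "make_toy_complex",
    "sample_markov_chain",
    "birth_death_reference",
    "two_basin_com_trace",
]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a small random two-chain complex.

    Defaults give a three-contact complex inside a 25 A cavity whose
    bound/unbound population ratio is of order one (P_b/P_u ~ 0.6,
    mirroring the confined two-body reference system) while still showing
    ~10 association/dissociation events per 10^5 integration steps.
    """

    nA: int = 8
    nB: int = 6
    n_contacts: int = 3
    seed: int = 0
    epsilon: float = 1.25  # kcal/mol per contact
    compactness: float = 6.0  # chain blob radius, A
    r_cavity: float = 25.0

    def __post_init__(self):
        if self.nA < 1 or self.nB < 1:
            raise ValueError("bead counts must be >= 1")
        if self.n_contacts > self.nA * self.nB:
            raise ValueError("n_contacts exceeds the number of inter-chain pairs")


def _random_blob(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points roughly uniformly inside a ball, kept >= 2.5 A apart."""
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(-radius, radius, size=3)
        if np.linalg.norm(p) > radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < 2.5:
            continue
        pts.append(p)
    return np.array(pts)


def make_toy_complex(spec: ToyComplexSpec):
    """Build a toy complex and its bound reference pose, deterministic per seed.

    Chain A is a compact blob at the origin; chain B is a compact blob placed
    along +x so the chains nearly touch.  The ``n_contacts`` closest
    inter-chain pairs of this bound pose become Go contacts with
    r_min equal to their bound-pose distance, making the bound pose the
    joint minimum of the contact energy.

    Returns ``(complex, bound_pose)`` where ``bound_pose`` is the (nA+nB, 3)
    reference coordinate array.
    """
    rng = np.random.default_rng(spec.seed)
    A = _random_blob(rng, spec.nA, spec.compactness)
    A -= A.mean(axis=0)
    B = _random_blob(rng, spec.nB, spec.compactness * max(0.8, spec.nB / spec.nA))
    B -= B.mean(axis=0)
    # slide B along +x until closest approach ~ 5 A
    gap_target = 5.0
    shift = A[:, 0].max() - B[:, 0].min() + gap_target
    B = B + np.array([shift, 0.0, 0.0])
    for _ in range(200):
        d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
        dmin = d.min()
        if abs(dmin - gap_target) < 0.05:
            break
        B[:, 0] += 0.5 * (gap_target - dmin)

    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    flat = np.argsort(d, axis=None)[: spec.n_contacts]
    contacts = []
    for f in flat:
        ia, ib = np.unravel_index(f, d.shape)
        contacts.append((int(ia), int(ib), float(d[ia, ib]), spec.epsilon))

    cplx = build_complex(
        A, B, contacts,
        restraints=RestraintSpec(),
        confinement=ConfinementSphere(r_cavity=spec.r_cavity),
    )
    return cplx, cplx.reference.copy()


def sample_markov_chain(T: np.ndarray, n_steps: int, seed: int = 0, start: int = 0) -> np.ndarray:
    """Sample a discrete trajectory of length ``n_steps`` from chain ``T``."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1] or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("T must be square and row-stochastic")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    out = np.empty(n_steps, dtype=int)
    s = int(start)
    u = rng.random(n_steps)
    for t in range(n_steps):
        out[t] = s
        s = int(np.searchsorted(cum[s], u[t]))
    return out


@dataclass
class BirthDeathReference:
    """Nearest-neighbor Metropolis chain with exact Boltzmann equilibrium."""

    energies: np.ndarray  # k_BT units
    attempt_prob: float
    T: np.ndarray
    analytic_pi: np.ndarray
    analytic_mfpt: np.ndarray  # state-to-state MFPT table in steps


def birth_death_reference(energies, attempt_prob: float = 0.5) -> BirthDeathReference:
    """Construct the Metropolis birth-death chain over the given state
    energies (k_BT units) with per-step move attempt probability
    ``attempt_prob`` to each neighbor; the diagonal absorbs the rest.

    analytic_pi is the exact Boltzmann distribution; the MFPT table comes
    from the nearest-neighbor first-step recursion and is verified against a
    dense linear solve to 1e-10.
    """
    E = np.asarray(energies, dtype=float)
    n = len(E)
    if n < 2:
        raise ValueError("need at least 2 states")
    if not 0 < attempt_prob <= 0.5:
        raise ValueError("attempt_prob must lie in (0, 0.5]")
    T = np.zeros((n, n))
    for i in range(n):
        for j in (i - 1, i + 1):
            if 0 <= j < n:
                T[i, j] = attempt_prob * min(1.0, np.exp(-(E[j] - E[i])))
        T[i, i] = 1.0 - T[i].sum()
    pi = np.exp(-(E - E.min()))
    pi /= pi.sum()

    mfpt = _birth_death_mfpt_recursion(T, pi)
    dense = _mfpt_dense_table(T)
    if np.max(np.abs(mfpt - dense)) > 1e-10 * max(1.0, dense.max()):
        raise AssertionError("birth-death MFPT recursion disagrees with dense solve")
    return BirthDeathReference(energies=E, attempt_prob=attempt_prob, T=T,
                               analytic_pi=pi, analytic_mfpt=mfpt)


def _birth_death_mfpt_recursion(T: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """MFPT table for a nearest-neighbor chain by the classical sum formula.

    For a birth-death chain, MFPT(i -> i+1) = (1 / (pi_i p_i)) * sum_{k<=i} pi_k
    with p_i = T[i, i+1]; longer passages add telescopically.
    """
    n = len(T)
    up = np.zeros(n - 1)  # MFPT(i -> i+1)
    down = np.zeros(n - 1)  # MFPT(i+1 -> i)
    cum = np.cumsum(pi)
    for i in range(n - 1):
        up[i] = cum[i] / (pi[i] * T[i, i + 1])
    rcum = np.cumsum(pi[::-1])[::-1]
    for i in range(n - 1):
        down[i] = rcum[i + 1] / (pi[i + 1] * T[i + 1, i])
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i < j:
                M[i, j] = up[i:j].sum()
            elif i > j:
                M[i, j] = down[j:i].sum()
    return M


def _mfpt_dense_table(T: np.ndarray) -> np.ndarray:
    n = len(T)
    M = np.zeros((n, n))
    for j in range(n):
        rest = [i for i in range(n) if i != j]
        A = np.eye(n - 1) - T[np.ix_(rest, rest)]
        tau = np.linalg.solve(A, np.ones(n - 1))
        for k, i in enumerate(rest):
            M[i, j] = tau[k]
    return M


def two_basin_com_trace(
    n_frames: int,
    frame_interval: float = 0.5,
    seed: int = 0,
    bound_mean: float = 22.0,
    bound_sigma: float = 2.8,
    unbound_mean: float = 50.0,
    unbound_sigma: float = 8.4,
    bound_lifetime: float = 60.0,
    unbound_lifetime: float = 120.0,
    relax_time: float = 2.0,
) -> np.ndarray:
    """Jump-diffusion COM-distance trace with a known basin boundary.

    The trace alternates between a bound and an unbound basin (exponential
    dwell times, ns), relaxing within each basin as an Ornstein-Uhlenbeck
    process (``relax_time`` ns).  With the defaults both basin edges sit
    2.5 sigma from 29 A, so 29 A is the noise-minimizing separatrix.
    Returns the distance series in Angstrom.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_frames)
    bound = rng.random() < 0.5
    mean, sig = (bound_mean, bound_sigma) if bound else (unbound_mean, unbound_sigma)
    x = mean
    a = np.exp(-frame_interval / relax_time)
    b = np.sqrt(1 - a * a)
    switch_p_b = frame_interval / bound_lifetime
    switch_p_u = frame_interval / unbound_lifetime
    for t in range(n_frames):
        if rng.random() < (switch_p_b if bound else switch_p_u):
            bound = not bound
            mean, sig = (bound_mean, bound_sigma) if bound else (unbound_mean, unbound_sigma)
        x = mean + a * (x - mean) + b * sig * rng.standard_normal()
        out[t] = abs(x)
    return out
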