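"""Markov state model estimation and binding observables.

Transition counting is sliding-window; estimation restricts to the largest
strongly connected component of the count graph and supports either plain
row normalization or the reversible maximum-likelihood estimate satisfying
detailed balance pi_i T_ij = pi_j T_ji.  On top of the transition matrix the
module computes the stationary distribution, implied timescales, PCCA+
metastable memberships, set-to-set mean first passage times, and the binding
thermodynamics/kinetics of a confined two-body system:

    K_eq = (P_bound / P_unbound) * V,      V = (4/3) pi (r_cavity^3 - r_cut^3)
    dG_b = -k_B T ln(P_bound / P_unbound)
    k_on = 1 / (MFPT_on * C),  k_off = 1 / MFPT_off,   C = 1/V
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .constants import KB

__all__ = [
    "DiscreteTrajectory",
    "CountMatrix",
    "MarkovModel",
    "MetastableAssignment",
    "ObservableSet",
    "count_transitions",
    "estimate_transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "pcca_assign",
    "mfpt_between_sets",
    "bulk_volume",
    "binding_observables",
    "pmf_binding_constant",
    "bootstrap_errors",
]


@dataclass
class DiscreteTrajectory:
    """Microstate index sequence with its saved-frame interval (ns)."""

    states: np.ndarray
    frame_interval: float

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D sequence")
        if np.any(self.states < 0):
            raise ValueError("state indices must be non-negative")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class CountMatrix:
    counts: np.ndarray
    lag: int
    frame_interval: float
    mode: str = "sliding"


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix on the active state set."""

    T: np.ndarray
    lag_time: float  # ns
    pi: np.ndarray
    eigenvalues: np.ndarray
    active_set: np.ndarray  # model index -> original state label
    reversible: bool = True
    counts: CountMatrix | None = None

    def __post_init__(self):
        n = len(self.T)
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(self.pi < -1e-15) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be a probability vector")
        if np.max(np.abs(self.pi @ self.T - self.pi)) > 1e-10:
            raise ValueError("pi is not stationary for T")

    @property
    def n_states(self) -> int:
        return len(self.T)


@dataclass
class MetastableAssignment:
    memberships: np.ndarray  # n x m, rows sum to 1
    crisp_labels: np.ndarray  # per-state argmax


@dataclass
class ObservableSet:
    """Binding thermodynamics and kinetics of a two-body confined model."""

    P_bound: float
    P_unbound: float
    K_eq: float  # A^3
    dG_b: float  # kcal/mol
    mfpt_on: float  # s
    mfpt_off: float  # s
    k_on: float  # A^3 s^-1
    k_off: float  # s^-1
    V: float  # A^3
    concentration: float  # A^-3
    kBT: float  # kcal/mol


def count_transitions(dtrajs: list[DiscreteTrajectory], lag: int) -> CountMatrix:
    """Sliding-window transition counts summed over trajectories."""
    if not dtrajs:
        raise ValueError("no trajectories")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    for d in dtrajs:
        if len(d) <= lag:
            raise ValueError(f"lag {lag} >= trajectory length {len(d)}")
    n = int(max(d.states.max() for d in dtrajs)) + 1
    C = np.zeros((n, n))
    for d in dtrajs:
        s = d.states
        np.add.at(C, (s[:-lag], s[lag:]), 1.0)
    return CountMatrix(counts=C, lag=lag, frame_interval=dtrajs[0].frame_interval)


def _largest_connected_set(C: np.ndarray) -> np.ndarray:
    """Largest strongly connected component among states with any counts."""
    visited = np.where((C.sum(axis=0) + C.sum(axis=1)) > 0)[0]
    if len(visited) == 0:
        raise ValueError("empty count matrix")
    sub = C[np.ix_(visited, visited)]
    ncomp, labels = connected_components(sp.csr_matrix(sub > 0), directed=True, connection="strong")
    sizes = np.bincount(labels)
    # tie-break: keep the component with the most counts
    best, best_w = 0, -1.0
    for comp in range(ncomp):
        members = visited[labels == comp]
        w = C[np.ix_(members, members)].sum()
        if w > best_w:
            best, best_w = comp, w
    active = visited[labels == best]
    if C[np.ix_(active, active)].sum() == 0:
        raise ValueError("no connected set with transition counts")
    return np.sort(active)


def _reversible_mle(C: np.ndarray, tol: float = 1e-12, max_iter: int = 1_000_000):
    """Self-consistent reversible MLE via the symmetric-flux iteration
    x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j)."""
    Csym = C + C.T
    c_row = C.sum(axis=1)
    x = Csym / Csym.sum()
    x_row = x.sum(axis=1)
    nz = Csym > 0
    for _ in range(max_iter):
        q = c_row / x_row
        denom = q[:, None] + q[None, :]
        x_new = np.where(nz, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        x_new /= x_new.sum()
        x_row_new = x_new.sum(axis=1)
        delta = np.max(np.abs(x_row_new - x_row))
        x, x_row = x_new, x_row_new
        if delta < tol:
            break
    T = x / x_row[:, None]
    pi = x_row / x_row.sum()
    return T, pi


def estimate_transition_matrix(counts: CountMatrix, reversible: bool = True) -> MarkovModel:
    """Estimate a Markov model on the largest strongly connected set."""
    C = counts.counts
    active = _largest_connected_set(C)
    Ca = C[np.ix_(active, active)]
    if reversible:
        T, pi = _reversible_mle(Ca)
    else:
        T = Ca / Ca.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
    # clean tiny numerical drift
    T = np.maximum(T, 0.0)
    T /= T.sum(axis=1, keepdims=True)
    pi = _stationary_from_T(T)
    evals = np.sort(np.linalg.eigvals(T).real)[::-1]
    lag_time = counts.lag * counts.frame_interval
    return MarkovModel(
        T=T, lag_time=lag_time, pi=pi, eigenvalues=evals,
        active_set=active, reversible=reversible, counts=counts,
    )


def _stationary_from_T(T: np.ndarray) -> np.ndarray:
    n = len(T)
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.maximum(pi, 0.0)
    return pi / pi.sum()


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Unique probability vector with pi T = pi; errors on reducible T."""
    T = np.asarray(T, dtype=float)
    ncomp, _ = connected_components(sp.csr_matrix(T > 0), directed=True, connection="strong")
    if ncomp > 1:
        raise ValueError("transition matrix is reducible; stationary distribution not unique")
    return _stationary_from_T(T)


def implied_timescales(model: MarkovModel, k: int):
    """Implied timescales t_i = -lag/ln(lambda_i) for the k eigenvalues below
    the Perron root, in ns; eigenvalues >= 1 reported as inf and flagged."""
    if k >= model.n_states:
        raise ValueError("k must be smaller than the number of states")
    lam = model.eigenvalues[1 : k + 1]
    ts, flags = [], []
    for v in lam:
        if v >= 1.0 - 1e-15:
            ts.append(np.inf)
            flags.append(True)
        elif v <= 0:
            ts.append(0.0)
            flags.append(True)
        else:
            ts.append(-model.lag_time / np.log(v))
            flags.append(False)
    return np.array(ts), np.array(flags)


def pcca_assign(model: MarkovModel, m: int) -> MetastableAssignment:
    """PCCA+ fuzzy memberships into ``m`` metastable sets.

    Uses the simplex-vertex construction on the m dominant right
    eigenvectors of the reversible transition matrix.
    """
    n = model.n_states
    if m < 2:
        raise ValueError("m must be >= 2 (a 1-set decomposition is undefined)")
    if m > n:
        raise ValueError("m cannot exceed the number of states")
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible model")

    # symmetrize in the pi inner product for stable real eigenvectors
    pi = model.pi
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * model.T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    V = V[:, order[:m]]
    X = V / sqrt_pi[:, None]  # right eigenvectors of T
    X /= np.sign(X[0, 0]) or 1.0
    X[:, 0] = 1.0

    # inner-simplex vertex search
    vertices = [int(np.argmax(np.linalg.norm(X - X.mean(axis=0), axis=1)))]
    Y = X - X[vertices[0]]
    for _ in range(1, m):
        norms = np.linalg.norm(Y, axis=1)
        v = int(np.argmax(norms))
        vertices.append(v)
        u = Y[v] / (norms[v] if norms[v] > 0 else 1.0)
        Y = Y - np.outer(Y @ u, u)

    A = np.linalg.solve(X[vertices], np.eye(m))
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    return MetastableAssignment(memberships=chi, crisp_labels=np.argmax(chi, axis=1))


def mfpt_between_sets(model: MarkovModel, source, target) -> float:
    """Mean first passage time from ``source`` to ``target`` in ns.

    Solves the first-step linear system for per-state MFPTs (zero on the
    target), then averages over the source set with the stationary
    distribution restricted to the source and renormalized.
    """
    source = np.asarray(sorted(set(source)), dtype=int)
    target = np.asarray(sorted(set(target)), dtype=int)
    n = model.n_states
    if len(source) == 0 or len(target) == 0:
        raise ValueError("source and target must be non-empty")
    if np.intersect1d(source, target).size:
        raise ValueError("source and target sets overlap")
    if source.max() >= n or target.max() >= n:
        raise ValueError("state index outside the active set")

    T = model.T
    m = np.zeros(n)
    rest = np.setdiff1d(np.arange(n), target)
    A = np.eye(len(rest)) - T[np.ix_(rest, rest)]
    tau = np.linalg.solve(A, np.ones(len(rest)))
    m[rest] = tau
    w = model.pi[source]
    return float(np.dot(w / w.sum(), m[source]) * model.lag_time)


def bulk_volume(r_cavity: float, r_cut: float) -> float:
    """Bulk (unbound) volume V = (4/3) pi (r_cavity^3 - r_cut^3), A^3."""
    if not 0 <= r_cut < r_cavity:
        raise ValueError("require 0 <= r_cut < r_cavity")
    return 4.0 / 3.0 * np.pi * (r_cavity**3 - r_cut**3)


def binding_observables(
    model: MarkovModel,
    bound_set,
    r_cavity: float,
    r_cut: float,
    temperature: float = 300.0,
) -> ObservableSet:
    """Equilibrium and kinetic binding observables from a Markov model."""
    bound = np.asarray(sorted(set(bound_set)), dtype=int)
    n = model.n_states
    if len(bound) == 0 or len(bound) >= n:
        raise ValueError("bound_set must be a non-empty proper subset of the active set")
    unbound = np.setdiff1d(np.arange(n), bound)

    kbt = KB * temperature
    P_b = float(model.pi[bound].sum())
    P_u = float(model.pi[unbound].sum())
    V = bulk_volume(r_cavity, r_cut)
    C = 1.0 / V
    K_eq = (P_b / P_u) * V
    dG = -kbt * np.log(P_b / P_u)
    mfpt_on_ns = mfpt_between_sets(model, unbound, bound)
    mfpt_off_ns = mfpt_between_sets(model, bound, unbound)
    mfpt_on = mfpt_on_ns * 1e-9  # s
    mfpt_off = mfpt_off_ns * 1e-9
    return ObservableSet(
        P_bound=P_b, P_unbound=P_u, K_eq=K_eq, dG_b=float(dG),
        mfpt_on=mfpt_on, mfpt_off=mfpt_off,
        k_on=1.0 / (mfpt_on * C), k_off=1.0 / mfpt_off,
        V=V, concentration=C, kBT=kbt,
    )


def pmf_binding_constant(profile, r_cut: float, temperature: float = 300.0) -> float:
    """Binding constant from a radial PMF: K_eq = int_0^rcut 4 pi r^2 e^(-W/kBT) dr.

    ``profile`` is a sequence of (r, W) pairs, W in kcal/mol, offset so the
    long-range tail is ~0 (warned if |W(tail)| > 0.1 kBT).
    """
    prof = np.asarray(profile, dtype=float)
    if prof.ndim != 2 or prof.shape[1] != 2:
        raise ValueError("profile must be (r, W) pairs")
    r, W = prof[:, 0], prof[:, 1]
    order = np.argsort(r)
    r, W = r[order], W[order]
    if r[0] > 1e-9 or r[-1] < r_cut - 1e-9:
        raise ValueError(f"profile must cover [0, {r_cut}]")
    kbt = KB * temperature
    if abs(W[-1]) > 0.1 * kbt:
        import warnings

        warnings.warn("PMF tail is not near zero; K_eq may be offset-biased", RuntimeWarning)
    mask = r <= r_cut + 1e-12
    rr, ww = r[mask], W[mask]
    if rr[-1] < r_cut - 1e-12:  # close the integral exactly at r_cut
        rr = np.append(rr, r_cut)
        ww = np.append(ww, np.interp(r_cut, r, W))
    integrand = 4.0 * np.pi * rr**2 * np.exp(-ww / kbt)
    return float(np.trapezoid(integrand, rr))


def bootstrap_errors(inputs: list, estimator, n_boot: int, seed: int = 0):
    """Bootstrap over whole trajectories: resample with replacement, re-run
    the estimator, return (mean, SD) of the successful replicates together
    with the number of failures."""
    if len(inputs) < 2:
        raise ValueError("need at least 2 trajectories to bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    vals, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(inputs), size=len(inputs))
        sample = [inputs[i] for i in idx]
        try:
            vals.append(estimator(sample))
        except Exception:
            failures += 1
    if not vals:
        raise RuntimeError(f"estimator failed on all {n_boot} bootstrap resamples")
    vals = np.asarray(vals, dtype=float)
    return float(vals.mean()), float(vals.std(ddof=1)), failures
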