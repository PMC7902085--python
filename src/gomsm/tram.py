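"""Multi-ensemble reweighting (TRAM) of biased and unbiased trajectories.

TRAM jointly estimates, from discrete trajectories generated in several
thermodynamic ensembles (here: unbiased Langevin runs and umbrella windows),
one set of unbiased microstate probabilities together with a reversible
transition matrix for every ensemble.  Inputs per ensemble are the
transition counts at the chosen lag and, per frame, the reduced bias
energies u_l(x)/k_BT of that frame evaluated in *every* ensemble l.

The estimator maximizes the joint likelihood of (i) reversible Markov
transitions within each ensemble k, with equilibrium weights
pi_i^k = e^{-f_i^k}, and (ii) the observed frames under discretization
consistency e^{-f_i^k} = sum_{x in X_i} mu(x) e^{-b^k(x)}, where X_i holds
every frame (from any ensemble) assigned to microstate i and mu are
unbiased sample weights.  Stationarity of the likelihood yields the
self-consistent scheme iterated here in log space:

    T^k_ij = (c^k_ij + c^k_ji) e^{f_i^k} / (v_i^k e^{f_i^k} + v_j^k e^{f_j^k})
    v_i^k  <- v_i^k sum_j T^k_ij                      (row normalization)
    R_i^k  = sum_j (c^k_ij + c^k_ji) v_j^k e^{f_j^k} /
                   (v_i^k e^{f_i^k} + v_j^k e^{f_j^k}) + N_i^k - col_i^k
    e^{-f_i^k} <- sum_{x in X_i} e^{-b^k(x)} /
                   sum_l R_i^l e^{f_i^l - b^l(x)}      (MBAR-like coupling)

with N_i^k the frame count and col_i^k the transition-arrival count of
state i in ensemble k.  With a single unbiased ensemble the fixed point is
exactly the reversible maximum-likelihood MSM; with no transition counts it
is exactly MBAR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .constants import KB
from .msm import DiscreteTrajectory, count_transitions

__all__ = ["EnsembleData", "TRAMModel", "estimate_tram", "free_energy_profile"]


@dataclass
class EnsembleData:
    """Trajectories of one thermodynamic ensemble plus their bias matrix.

    ``bias`` stacks, over all frames of all ``dtrajs`` (in order), the
    reduced bias energies (k_BT units) of each frame evaluated in every
    ensemble of the campaign; an unbiased ensemble contributes an
    identically zero column.  ``ensemble_id`` is the column index of the
    ensemble that generated these trajectories.
    """

    dtrajs: list[DiscreteTrajectory]
    bias: np.ndarray  # (total frames, n_ensembles)
    ensemble_id: int

    def __post_init__(self):
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.ndim != 2:
            raise ValueError("bias must be a (frames, ensembles) matrix")
        total = sum(len(d) for d in self.dtrajs)
        if self.bias.shape[0] != total:
            raise ValueError(
                f"bias matrix has {self.bias.shape[0]} rows but trajectories hold {total} frames"
            )


@dataclass
class TRAMModel:
    """Converged TRAM estimate."""

    state_free_energies: np.ndarray  # (n_ensembles, n_states), k_BT units
    unbiased_pi: np.ndarray
    transition_matrices: np.ndarray  # (n_ensembles, n_states, n_states)
    active_set: np.ndarray
    lag: int
    converged: bool
    final_increment: float
    n_iterations: int


def _union_connected_set(count_mats: np.ndarray) -> np.ndarray:
    """States of the largest component of the union count graph; raises if
    the visited-state graph splits into several components."""
    union = count_mats.sum(axis=0)
    union = union + union.T
    visited = np.where(union.sum(axis=1) > 0)[0]
    if len(visited) == 0:
        raise ValueError("no transition counts at this lag")
    sub = union[np.ix_(visited, visited)]
    ncomp, labels = connected_components(sp.csr_matrix(sub > 0), directed=False)
    if ncomp > 1:
        groups = [visited[labels == c].tolist() for c in range(ncomp)]
        raise ValueError(
            "microstate space is disconnected across ensembles; "
            f"disconnected state groups: {groups}"
        )
    return visited


def estimate_tram(
    ensembles: list[EnsembleData],
    lag: int,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> TRAMModel:
    """Run the TRAM self-consistent iteration to tolerance ``tol`` (k_BT)."""
    if not ensembles:
        raise ValueError("need at least one ensemble")
    K = ensembles[0].bias.shape[1]
    n_all = 1 + max(int(d.states.max()) for e in ensembles for d in e.dtrajs)

    C = np.zeros((K, n_all, n_all))
    N = np.zeros((K, n_all))
    for e in ensembles:
        k = e.ensemble_id
        cm = count_transitions(e.dtrajs, lag)
        m = cm.counts.shape[0]
        C[k, :m, :m] += cm.counts
        for d in e.dtrajs:
            N[k] += np.bincount(d.states, minlength=n_all)

    active = _union_connected_set(C)
    amap = -np.ones(n_all, dtype=int)
    amap[active] = np.arange(len(active))
    n = len(active)
    C = C[:, active][:, :, active]
    N = N[:, active]

    # flatten frames belonging to active states, sorted by state for
    # segment-wise (per-microstate) log-sum-exp reductions
    all_states = []
    all_bias = []
    for e in ensembles:
        st = amap[np.concatenate([d.states for d in e.dtrajs])]
        keep = st >= 0
        all_states.append(st[keep])
        all_bias.append(e.bias[keep])
    states = np.concatenate(all_states)
    bias = np.vstack(all_bias)  # (F, K)
    order = np.argsort(states, kind="stable")
    states, bias = states[order], bias[order]
    seg_starts = np.searchsorted(states, np.arange(n))
    # every active state has frames (it has counts, hence visits)
    frame_state = states

    Csym = C + np.transpose(C, (0, 2, 1))
    col = C.sum(axis=1)  # arrivals per (k, i)
    has_pair = Csym > 0
    with np.errstate(divide="ignore"):
        log_Csym = np.where(has_pair, np.log(np.maximum(Csym, 1e-300)), -np.inf)
        extra = N - col  # frame surplus, >= 0 for sliding counts
        log_extra = np.where(extra > 0, np.log(np.maximum(extra, 1e-300)), -np.inf)

    f = np.zeros((K, n))
    row_tot = Csym.sum(axis=2)
    log_v = np.where(row_tot > 0, np.log(np.maximum(0.5 * row_tot, 1e-300)), -np.inf)

    def _pair_denom(log_v_, f_):
        # log(v_i e^{f_i} + v_j e^{f_j}) over (k, i, j)
        a = log_v_ + f_
        return np.logaddexp(a[:, :, None], a[:, None, :])

    increment = np.inf
    converged = False
    it = 0
    # -inf - -inf = nan appears transiently in masked (no-pair) entries
    old_err = np.seterr(invalid="ignore")
    for it in range(1, max_iter + 1):
        # --- Lagrange multipliers (row normalization of each T^k) ---
        denom = _pair_denom(log_v, f)
        terms = np.where(has_pair, log_Csym - denom, -np.inf)
        new_log_v = log_v + f + logsumexp(terms, axis=2)
        new_log_v = np.where(row_tot > 0, new_log_v, -np.inf)

        # --- R factors ---
        denom = _pair_denom(new_log_v, f)
        trans = np.where(
            has_pair, log_Csym + (new_log_v + f)[:, None, :] - denom, -np.inf
        )
        log_R = np.logaddexp(logsumexp(trans, axis=2), log_extra)  # (K, n)

        # --- free energies, MBAR-like coupling over all frames ---
        M = log_R[:, frame_state].T + f[:, frame_state].T - bias  # (F, K)
        log_den = logsumexp(M, axis=1)  # per frame
        A = -bias - log_den[:, None]  # (F, K)
        seg_max = np.maximum.reduceat(A, seg_starts, axis=0)
        seg_sum = np.add.reduceat(np.exp(A - seg_max[frame_state]), seg_starts, axis=0)
        new_f = -(seg_max + np.log(seg_sum)).T  # (K, n)

        # gauge: normalize ensemble 0 so sum_i e^{-f_i^0} = 1
        s = logsumexp(-new_f[0])
        new_f += s
        new_log_v -= s

        # convergence is measured on the (gauge-fixed) free energies only:
        # the Lagrange multipliers may drift indefinitely when a
        # within-ensemble transition-matrix MLE sits on the simplex boundary
        # (entries tending to 0 or 1), while every reported estimate —
        # f, R, pi and the transition matrices — still converges
        increment = float(np.max(np.abs(new_f - f)))
        f, log_v = new_f, new_log_v
        if increment < tol:
            converged = True
            break
    if not converged:
        np.seterr(**old_err)
        raise RuntimeError(
            f"TRAM did not converge in {max_iter} iterations (last increment {increment:.3e})"
        )

    # unbiased stationary distribution: mu(x) = 1 / sum_l R^l e^{f^l - b^l};
    # pi_i proportional to the zero-bias weight of state i's frames
    denom = _pair_denom(log_v, f)
    trans = np.where(has_pair, log_Csym + (log_v + f)[:, None, :] - denom, -np.inf)
    log_R = np.logaddexp(logsumexp(trans, axis=2), log_extra)
    M = log_R[:, frame_state].T + f[:, frame_state].T - bias
    log_den = logsumexp(M, axis=1)
    A = -log_den
    seg_max = np.maximum.reduceat(A, seg_starts)
    seg_sum = np.add.reduceat(np.exp(A - seg_max[frame_state]), seg_starts)
    log_mu = seg_max + np.log(seg_sum)
    pi = np.exp(log_mu - logsumexp(log_mu))

    # per-ensemble reversible transition matrices
    Tmats = np.zeros((K, n, n))
    for k in range(K):
        with np.errstate(invalid="ignore"):
            logT = np.where(
                has_pair[k],
                log_Csym[k] + f[k][:, None]
                - np.logaddexp((log_v[k] + f[k])[:, None], (log_v[k] + f[k])[None, :]),
                -np.inf,
            )
        T = np.exp(logT)
        empty = row_tot[k] == 0
        T[empty] = 0.0
        T[empty, empty] = 1.0
        rowsum = T.sum(axis=1)
        T /= rowsum[:, None]
        Tmats[k] = T

    np.seterr(**old_err)
    return TRAMModel(
        state_free_energies=f,
        unbiased_pi=pi,
        transition_matrices=Tmats,
        active_set=active,
        lag=lag,
        converged=converged,
        final_increment=float(increment),
        n_iterations=it,
    )


def free_energy_profile(pi: np.ndarray, bin_map, temperature: float = 300.0):
    """Project microstate probabilities onto feature bins.

    ``bin_map`` maps microstate index -> bin index (array-like).  Returns
    ``(bin_indices, W)`` with W_b = -k_BT ln sum_{i in b} pi_i in kcal/mol,
    offset so min W = 0; empty bins carry NaN.
    """
    pi = np.asarray(pi, dtype=float)
    bin_map = np.asarray(bin_map, dtype=int)
    if bin_map.shape != pi.shape:
        raise ValueError("bin_map must assign a bin to every microstate")
    nbins = int(bin_map.max()) + 1
    mass = np.zeros(nbins)
    np.add.at(mass, bin_map, pi)
    if np.all(mass == 0):
        raise ValueError("all bins empty")
    kbt = KB * temperature
    with np.errstate(divide="ignore"):
        W = -kbt * np.log(mass)
    W[mass == 0] = np.nan
    W -= np.nanmin(W)
    return np.arange(nbins), W
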