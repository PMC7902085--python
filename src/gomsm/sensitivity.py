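"""Sensitivity of MSM observables to transition-matrix uncertainty.

Local sensitivities are the derivatives of an observable (here the entries
of the stationary distribution) with respect to the transition-matrix
elements, computed under the row-compensation convention: a perturbation of
an off-diagonal element T_jk is absorbed by the diagonal T_jj so perturbed
matrices stay stochastic.  Statistical uncertainty of the matrix itself is
modelled as independent per-row Dirichlet posteriors over the observed
transition counts.  Propagating the row covariances through the local
derivatives gives a first-order variance-based (Sobol) global sensitivity
per observable; aggregating over the observables localized on each
microstate ranks the microstates whose poor sampling contributes most
error, and the ranked states' average COM distances select the umbrella
windows worth adding to a focused TRAM estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msm import CountMatrix, MarkovModel
from .simulate import WindowSet

__all__ = [
    "LocalSensitivity",
    "TransitionCovariance",
    "GlobalSensitivity",
    "WindowSelection",
    "local_sensitivity_stationary",
    "transition_matrix_covariance",
    "global_sensitivity",
    "select_windows",
]


@dataclass
class LocalSensitivity:
    """S[i, j, k] = d pi_i / d T_jk under row compensation (T_jj absorbs)."""

    tensor: np.ndarray  # (n_obs, n, n)
    observable: str = "stationary_distribution"


@dataclass
class TransitionCovariance:
    """Per-row Dirichlet posterior covariance blocks; zero across rows."""

    row_blocks: np.ndarray  # (n, n, n): row i -> cov[T_ij, T_il]
    total_counts: np.ndarray  # effective per-row counts


@dataclass
class GlobalSensitivity:
    per_observable: np.ndarray  # S_global per observable (>= 0)
    per_state: np.ndarray  # aggregate localized on each state's pi entry


@dataclass
class WindowSelection:
    ranked_states: np.ndarray
    com_of_state: np.ndarray
    selected_centers: np.ndarray
    coverage: float


def local_sensitivity_stationary(model: MarkovModel) -> LocalSensitivity:
    """d pi_i / d T_jk for all i, j, k via the fundamental-matrix solve.

    With the row-compensated perturbation E = e_j (e_k - e_j)^T the
    first-order response is d pi = pi E Z with Z = (I - T + 1 pi)^(-1),
    hence d pi_i / d T_jk = pi_j (Z_ki - Z_ji).
    """
    T, pi = model.T, model.pi
    n = len(T)
    Z = np.linalg.inv(np.eye(n) - T + np.outer(np.ones(n), pi))
    # S[i, j, k] = pi_j (Z[k, i] - Z[j, i])
    S = np.empty((n, n, n))
    for j in range(n):
        S[:, j, :] = pi[j] * (Z - Z[j][None, :]).T
    return LocalSensitivity(tensor=S)


def transition_matrix_covariance(counts: CountMatrix, prior: float = 0.0) -> TransitionCovariance:
    """Per-row Dirichlet posterior covariance of the transition matrix.

    Row i of T, given counts c_i. + prior, is Dirichlet; its covariance is
    cov[T_ij, T_il] = Tbar_ij (delta_jl - Tbar_il) / (c_i + alpha n + 1).
    Rows are independent, so cross-row covariances vanish.
    """
    C = counts.counts
    n = C.shape[0]
    alpha_row = C + prior
    tot = alpha_row.sum(axis=1)
    if np.any(tot <= 0):
        empty = np.where(tot <= 0)[0]
        raise ValueError(f"empty count rows with zero prior: {empty.tolist()}")
    Tbar = alpha_row / tot[:, None]
    blocks = np.empty((n, n, n))
    for i in range(n):
        blocks[i] = (np.diag(Tbar[i]) - np.outer(Tbar[i], Tbar[i])) / (tot[i] + 1.0)
    return TransitionCovariance(row_blocks=blocks, total_counts=tot)


def global_sensitivity(S: LocalSensitivity, cov: TransitionCovariance) -> GlobalSensitivity:
    """First-order Sobol propagation S_global(i) = sum S_i cov S_i.

    The covariance support is block-diagonal over rows, so
    S_global(i) = sum_j s_ij^T B_j s_ij with s_ij the j-th row slice of the
    local tensor and B_j the row-j Dirichlet block.
    """
    tensor = S.tensor
    blocks = cov.row_blocks
    if tensor.shape[1:] != blocks.shape[1:] or tensor.shape[1] != blocks.shape[0]:
        raise ValueError("incompatible shapes between sensitivities and covariance")
    # out[i] = sum_j tensor[i, j, :] @ blocks[j] @ tensor[i, j, :]
    tmp = np.einsum("ijk,jkl->ijl", tensor, blocks)
    out = np.einsum("ijl,ijl->i", tmp, tensor)
    out = np.maximum(out, 0.0)
    return GlobalSensitivity(per_observable=out, per_state=out.copy())


def select_windows(
    glob: GlobalSensitivity,
    com_of_state: np.ndarray,
    grid: WindowSet,
    coverage: float = 0.9,
) -> WindowSelection:
    """Convert per-state sensitivities into an umbrella-window selection.

    States are ranked by aggregate sensitivity (ties to smaller average
    COM); the smallest prefix accumulating at least ``coverage`` of the
    total is taken, and every grid center within that prefix's [min, max]
    average-COM span (inclusive) is selected.
    """
    s = np.asarray(glob.per_state, dtype=float)
    com = np.asarray(com_of_state, dtype=float)
    if s.shape != com.shape:
        raise ValueError("per-state sensitivities and COM map must align")
    total = s.sum()
    if total <= 0:
        raise ValueError("all sensitivities are zero")
    order = np.lexsort((com, -s))
    cum = np.cumsum(s[order]) / total
    n_take = int(np.searchsorted(cum, coverage - 1e-12) + 1)
    chosen = order[:n_take]
    lo, hi = com[chosen].min(), com[chosen].max()
    centers = np.asarray(grid.centers)
    sel = centers[(centers >= lo - 1e-9) & (centers <= hi + 1e-9)]
    return WindowSelection(
        ranked_states=order, com_of_state=com, selected_centers=sel, coverage=coverage
    )
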