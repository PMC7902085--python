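"""Featurization, long-lived-contact filtering, TICA and discretization.

The featurization layer turns bead trajectories into low-dimensional series:
the chain-chain COM distance (the binding reaction coordinate), its inverse
square (an indirect coordinate), inter-chain bead pair distances, and the
minimum RMSD to the native bound pose.  Time-lagged independent component
analysis (TICA) then extracts the slowest linear combinations of those
features by solving the generalized eigenproblem C(tau) U = C(0) U Lambda on
mean-free data; feature space is discretized into microstates by k-means,
with the number of clusters chosen by the elbow method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .simulate import RunResult, _com_distances

__all__ = [
    "FeatureSeries",
    "TICAModel",
    "Discretization",
    "geometry_features",
    "rmsd_min",
    "long_lived_contacts",
    "tica_fit",
    "tica_transform",
    "kmeans_cluster",
    "elbow_choose_k",
]


@dataclass
class FeatureSeries:
    """frames x d feature matrix with labels and the saved-frame interval (ns)."""

    values: np.ndarray
    names: list[str]
    frame_interval: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature value")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("one name per feature column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_text(self, path) -> None:
        header = f"frame_interval_ns={self.frame_interval!r}\n" + "\t".join(self.names)
        np.savetxt(path, self.values, header=header, delimiter="\t")

    @classmethod
    def from_text(cls, path) -> "FeatureSeries":
        with open(path) as fh:
            line1 = fh.readline().lstrip("# ").strip()
            line2 = fh.readline().lstrip("# ").strip()
        interval = float(line1.split("=", 1)[1])
        names = line2.split("\t")
        values = np.loadtxt(path, skiprows=2, delimiter="\t", ndmin=2)
        return cls(values=values, names=names, frame_interval=interval)


def _split_chains(run: RunResult):
    a = np.where(run.chain_ids == 0)[0]
    b = np.where(run.chain_ids == 1)[0]
    return a, b


def geometry_features(run: RunResult, mode: str = "com_distance", pairs=None) -> FeatureSeries:
    """Geometric features of a run.

    ``mode`` is one of ``com_distance`` (mass-weighted COM separation, A),
    ``inverse_sq_com`` (1/d^2, A^-2) or ``pair_distances`` (Euclidean
    distances for the given ``(iA, iB)`` per-chain bead index pairs, A).
    """
    if mode in ("com_distance", "inverse_sq_com"):
        d = _com_distances(run.frames, run.chain_ids, run.masses)
        if mode == "com_distance":
            return FeatureSeries(d[:, None], ["com_distance"], run.frame_interval)
        return FeatureSeries(1.0 / d[:, None] ** 2, ["inverse_sq_com"], run.frame_interval)
    if mode == "pair_distances":
        if not pairs:
            raise ValueError("pair_distances mode requires a non-empty pair list")
        ia, ib = _split_chains(run)
        cols, names = [], []
        for pA, pB in pairs:
            if not (0 <= pA < len(ia)) or not (0 <= pB < len(ib)):
                raise IndexError(f"invalid bead pair ({pA}, {pB})")
            dr = run.frames[:, ia[pA], :] - run.frames[:, ib[pB], :]
            cols.append(np.linalg.norm(dr, axis=1))
            names.append(f"d_A{pA}_B{pB}")
        return FeatureSeries(np.column_stack(cols), names, run.frame_interval)
    raise ValueError(f"unknown feature mode {mode!r}")


def rmsd_min(run: RunResult, reference: np.ndarray) -> FeatureSeries:
    """Per-frame minimum RMSD to ``reference`` over rigid rotations+translations."""
    ref = np.asarray(reference, dtype=float)
    if ref.shape != run.frames.shape[1:]:
        raise ValueError("reference bead count does not match trajectory")
    ref_c = ref - ref.mean(axis=0)
    out = np.empty(run.n_frames)
    with warnings.catch_warnings():
        # collinear/planar bead sets leave the optimal rotation degenerate;
        # the residual (hence the RMSD) is still unique
        warnings.filterwarnings("ignore", message="Optimal rotation is not")
        for t in range(run.n_frames):
            x = run.frames[t] - run.frames[t].mean(axis=0)
            _, rssd = Rotation.align_vectors(ref_c, x)
            out[t] = rssd / np.sqrt(len(ref))
    return FeatureSeries(out[:, None], ["rmsd_min"], run.frame_interval)


def long_lived_contacts(
    runs: list[RunResult], dist_cutoff: float = 12.0, min_lifetime: float = 1.0
) -> list[tuple[int, int]]:
    """Inter-chain bead pairs held below ``dist_cutoff`` for >= ``min_lifetime``.

    A pair qualifies if any single run contains a contiguous segment of
    frames with distance strictly below the cutoff whose duration is at
    least ``min_lifetime`` (ns).  Frames exactly at the cutoff count as
    unbound.
    """
    if not runs:
        raise ValueError("no runs given")
    kept: set[tuple[int, int]] = set()
    for run in runs:
        if min_lifetime < run.frame_interval:
            raise ValueError(
                f"min_lifetime {min_lifetime} ns is below the frame interval "
                f"{run.frame_interval} ns and cannot be resolved"
            )
        min_frames = int(np.ceil(min_lifetime / run.frame_interval))
        ia, ib = _split_chains(run)
        # (frames, nA, nB) distances
        dr = run.frames[:, ia, None, :] - run.frames[:, None, ib, :]
        dist = np.linalg.norm(dr, axis=-1)
        below = dist < dist_cutoff
        for pA in range(len(ia)):
            for pB in range(len(ib)):
                if (pA, pB) in kept:
                    continue
                if _longest_true_segment(below[:, pA, pB]) >= min_frames:
                    kept.add((pA, pB))
    return sorted(kept)


def _longest_true_segment(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    m = np.concatenate(([0], mask.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(m))
    return int((edges[1::2] - edges[::2]).max())


@dataclass
class TICAModel:
    """TICA solution: covariances, eigenpairs and implied timescales."""

    mean: np.ndarray
    C0: np.ndarray
    Ctau: np.ndarray
    lag: int
    eigenvectors: np.ndarray  # columns are ICs, ordered by eigenvalue desc
    eigenvalues: np.ndarray
    timescales: np.ndarray  # ns
    frame_interval: float


def _as_series_list(X) -> list[FeatureSeries]:
    if isinstance(X, FeatureSeries):
        return [X]
    return list(X)


def tica_fit(X, lag: int, ridge: float = 1e-8) -> TICAModel:
    """Fit TICA at integer frame lag ``lag``.

    Means are removed, the instantaneous and time-lagged covariances are
    estimated with 1/(N - tau - 1) normalization and the lagged one
    symmetrized, and the generalized eigenproblem C(tau) u = lambda C(0) u is
    solved with a small ridge on C(0)'s diagonal.  Implied timescales are
    -lag * frame_interval / ln|lambda|.
    """
    series = _as_series_list(X)
    if not series:
        raise ValueError("no input series")
    d = series[0].d
    interval = series[0].frame_interval
    for s in series:
        if s.n_frames <= lag:
            raise ValueError("every series must be longer than the lag")
        if s.d != d:
            raise ValueError("inconsistent feature dimension")

    ntot = sum(s.n_frames for s in series)
    mean = sum(s.values.sum(axis=0) for s in series) / ntot

    C0 = np.zeros((d, d))
    Ct = np.zeros((d, d))
    norm = 0
    for s in series:
        z = s.values - mean
        n = len(z)
        C0 += z[: n - lag].T @ z[: n - lag]
        Ct += z[: n - lag].T @ z[lag:]
        norm += n - lag - 1
    if norm <= 0:
        raise ValueError("insufficient data for covariance estimation")
    C0 /= norm
    Ct /= norm
    C0 = 0.5 * (C0 + C0.T)
    Ct = 0.5 * (Ct + Ct.T)

    reg = ridge * np.trace(C0) / d
    C0r = C0 + reg * np.eye(d)
    # diagnose null directions beyond the reach of regularization
    evals0 = np.linalg.eigvalsh(C0r)
    if np.any(evals0 <= 0):
        null = np.where(np.linalg.eigvalsh(C0) <= 0)[0]
        raise np.linalg.LinAlgError(
            f"C(0) is rank-deficient beyond regularization; null directions {null.tolist()}"
        )

    from scipy.linalg import eigh

    lam, U = eigh(Ct, C0r)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(
            np.abs(lam) >= 1.0, np.inf, -lag * interval / np.log(np.abs(lam))
        )
    return TICAModel(
        mean=mean, C0=C0, Ctau=Ct, lag=lag,
        eigenvectors=U, eigenvalues=lam, timescales=ts, frame_interval=interval,
    )


def tica_transform(model: TICAModel, X: FeatureSeries, n_components: int) -> FeatureSeries:
    """Project mean-free data onto the ``n_components`` slowest ICs."""
    if n_components > model.eigenvectors.shape[1]:
        raise ValueError("n_components exceeds the feature dimension")
    z = (X.values - model.mean) @ model.eigenvectors[:, :n_components]
    names = [f"IC{i + 1}" for i in range(n_components)]
    return FeatureSeries(z, names, X.frame_interval)


@dataclass
class Discretization:
    """k-means microstate assignment of feature space."""

    centers: np.ndarray
    assignments: np.ndarray
    inertia: float

    def __post_init__(self):
        if self.inertia < -1e-12:
            raise ValueError("inertia must be non-negative")

    @property
    def k(self) -> int:
        return len(self.centers)

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Nearest-center assignment, ties to the lowest center index."""
        X = np.atleast_2d(X)
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=-1)
        return np.argmin(d2, axis=1)


def kmeans_cluster(X: np.ndarray, k: int, seed: int = 0) -> Discretization:
    """Lloyd k-means from k-means++ initialization, deterministic per seed."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of points ({len(X)})")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    km.fit(X)
    disc = Discretization(
        centers=km.cluster_centers_, assignments=km.labels_.astype(int), inertia=float(km.inertia_)
    )
    # re-assign with the lowest-index tie-break convention
    disc.assignments = disc.assign(X)
    return disc


def elbow_choose_k(inertia_by_k: dict[int, float]) -> int:
    """Elbow criterion: k with maximum perpendicular distance to the chord
    joining the first and last (k, inertia) points."""
    if len(inertia_by_k) < 3:
        raise ValueError("need at least 3 candidate k values")
    ks = np.array(sorted(inertia_by_k))
    inert = np.array([inertia_by_k[k] for k in ks], dtype=float)
    if np.any(np.diff(inert) > 1e-12):
        raise ValueError("inertia must be non-increasing in k")
    p0 = np.array([ks[0], inert[0]])
    p1 = np.array([ks[-1], inert[-1]])
    chord = p1 - p0
    chord_len = np.linalg.norm(chord)
    pts = np.column_stack([ks, inert]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / chord_len
    if np.max(dist) < 1e-12 * max(1.0, abs(inert[0])):
        warnings.warn("degenerate elbow: inertia curve is linear", RuntimeWarning)
        return int(ks[1])
    return int(ks[np.argmax(dist)])
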