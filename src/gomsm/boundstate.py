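"""Bound-state cutoff determination from indicator autocorrelations.

A binary indicator h(t) marks frames whose chain-chain COM distance is at
or below a trial cutoff r_cut (the boundary counts as bound).  Its
normalized autocorrelation is fitted with a biexponential
A1 exp(-t/tau1) + A2 exp(-t/tau2); scanning r_cut and maximizing the slow
relaxation time tau2 (the bound-state lifetime) picks the cutoff least
contaminated by rapid boundary recrossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .features import FeatureSeries

__all__ = [
    "IndicatorSeries",
    "AutocorrCurve",
    "BiexpFit",
    "RcutScan",
    "bound_indicator",
    "indicator_autocorrelation",
    "fit_biexponential",
    "scan_rcut",
]


@dataclass
class IndicatorSeries:
    h: np.ndarray  # binary
    frame_interval: float  # ns

    def __post_init__(self):
        self.h = np.asarray(self.h)
        if not np.isin(self.h, (0, 1)).all():
            raise ValueError("indicator values must be 0 or 1")


@dataclass
class AutocorrCurve:
    lags: np.ndarray  # ns
    values: np.ndarray


@dataclass
class BiexpFit:
    A1: float
    A2: float
    tau1: float  # ns, fast
    tau2: float  # ns, slow
    residual: float
    degenerate: bool = False

    def __post_init__(self):
        if self.A1 < 0 or self.A2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 < self.tau1 <= self.tau2:
            raise ValueError("require 0 < tau1 <= tau2")


@dataclass
class RcutScan:
    grid: np.ndarray
    fits: list  # BiexpFit or None per grid point
    optimal_rcut: float


def bound_indicator(com: FeatureSeries, r_cut: float) -> IndicatorSeries:
    """h = 1 iff COM distance <= r_cut (boundary counts as bound)."""
    if r_cut < 0:
        raise ValueError("r_cut must be non-negative")
    d = com.values[:, 0]
    return IndicatorSeries(h=(d <= r_cut).astype(np.int8), frame_interval=com.frame_interval)


def indicator_autocorrelation(series: list[IndicatorSeries], max_lag: float) -> AutocorrCurve:
    """Aggregate normalized autocovariance of the indicator.

    Each trajectory's mean-subtracted, variance-normalized autocorrelation
    is computed separately (no cross-trajectory products) and the curves are
    combined by trajectory-length weighting.
    """
    if isinstance(series, IndicatorSeries):
        series = [series]
    if not series:
        raise ValueError("no indicator series")
    interval = series[0].frame_interval
    nlags = int(np.floor(max_lag / interval)) + 1
    acc = np.zeros(nlags)
    wsum = np.zeros(nlags)
    any_valid = False
    for s in series:
        h = s.h.astype(float)
        n = len(h)
        var = h.var()
        if var == 0 or n < 2:
            continue
        any_valid = True
        z = h - h.mean()
        # FFT autocovariance, biased normalization so C(0) = 1
        nfft = 1 << int(np.ceil(np.log2(2 * n)))
        fz = np.fft.rfft(z, nfft)
        full = np.fft.irfft(fz * np.conj(fz), nfft)[:n]
        ac = full / (n * var)
        m = min(nlags, n)
        w = float(n)
        acc[:m] += w * ac[:m]
        wsum[:m] += w
    if not any_valid:
        raise ValueError("all indicator series are constant (zero variance)")
    valid = wsum > 0
    lags = np.arange(nlags)[valid] * interval
    return AutocorrCurve(lags=lags, values=acc[valid] / wsum[valid])


def _loglinear_tau(lags, vals):
    """Crude decay time from a log-linear fit of the positive segment."""
    mask = vals > 1e-6
    if mask.sum() < 2:
        return max(lags[1] - lags[0], 1e-3)
    slope = np.polyfit(lags[mask], np.log(vals[mask]), 1)[0]
    return -1.0 / slope if slope < 0 else lags[mask][-1]


def fit_biexponential(curve: AutocorrCurve) -> BiexpFit:
    """Constrained least-squares fit of A1 e^(-t/tau1) + A2 e^(-t/tau2).

    Initialization takes the fast time from the head of the curve and the
    slow time from its tail; the result is reported with tau1 <= tau2, with
    a degeneracy flag when the two components are indistinguishable.
    """
    lags = np.asarray(curve.lags, dtype=float)
    vals = np.asarray(curve.values, dtype=float)
    if len(lags) < 5:
        raise ValueError("need at least 5 points to fit a biexponential")
    if not (np.isfinite(lags).all() and np.isfinite(vals).all()):
        raise ValueError("non-finite values in the autocorrelation curve")

    head = slice(0, max(3, len(lags) // 5))
    tail = slice(len(lags) // 2, len(lags))
    tau_fast = _loglinear_tau(lags[head], vals[head])
    tau_slow = max(_loglinear_tau(lags[tail], vals[tail]), 1.5 * tau_fast)
    a0 = max(vals[0], 1e-3)

    def biexp(t, A1, A2, t1, t2):
        return A1 * np.exp(-t / t1) + A2 * np.exp(-t / t2)

    p0 = (0.7 * a0, 0.3 * a0, tau_fast, tau_slow)
    bounds = ([0, 0, 1e-9, 1e-9], [np.inf, np.inf, np.inf, np.inf])
    try:
        popt, _ = curve_fit(biexp, lags, vals, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"biexponential fit did not converge (best iterate p0={p0})") from exc
    A1, A2, t1, t2 = popt
    if t1 > t2:
        A1, A2, t1, t2 = A2, A1, t2, t1
    resid = float(np.linalg.norm(biexp(lags, A1, A2, t1, t2) - vals))
    degenerate = bool(min(A1, A2) < 1e-3 * max(A1, A2) or abs(t2 - t1) < 1e-3 * t2)
    return BiexpFit(A1=float(A1), A2=float(A2), tau1=float(t1), tau2=float(t2),
                    residual=resid, degenerate=degenerate)


def scan_rcut(com_series: list[FeatureSeries], grid, max_lag: float) -> RcutScan:
    """Scan candidate cutoffs; the optimum maximizes the slow time tau2.

    Per grid point the pipeline is indicator -> aggregate autocorrelation ->
    biexponential fit.  Failed fits are recorded as None; ties in tau2 go to
    the smaller cutoff.
    """
    if isinstance(com_series, FeatureSeries):
        com_series = [com_series]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty r_cut grid")
    fits: list[BiexpFit | None] = []
    for rc in grid:
        try:
            ind = [bound_indicator(s, rc) for s in com_series]
            curve = indicator_autocorrelation(ind, max_lag)
            fits.append(fit_biexponential(curve))
        except (ValueError, RuntimeError):
            fits.append(None)
    ok = [(i, f) for i, f in enumerate(fits) if f is not None]
    if not ok:
        raise RuntimeError("biexponential fit failed at every grid point")
    best_i = max(ok, key=lambda t: (t[1].tau2, -grid[t[0]]))[0]
    return RcutScan(grid=grid, fits=fits, optimal_rcut=float(grid[best_i]))
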