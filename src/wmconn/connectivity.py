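"""Instantaneous phase and time-resolved wPLI connectivity.

The weighted phase lag index (wPLI) between two signals weights each
trial's phase difference by the magnitude of the imaginary component of
the cross-spectrum, making it insensitive to zero-lag (volume-conduction)
coupling. At each time sample ``t`` the cross-spectrum is estimated across
trials from single-sample analytic products,

    X_k(t) = z_i,k(t) * conj(z_j,k(t)),
    wPLI_ij(t) = | sum_k Im X_k(t) | / sum_k | Im X_k(t) |,

giving a value in [0, 1]: 0 for random phase differences, 1 for a constant
(sign-consistent) phase difference. When every imaginary component
vanishes (0/0) the value is defined as 0 — no phase-lag evidence.

This is the standard amplitude-weighted estimator; the debiased squared
variant is available via ``debiased=True``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal import hilbert

from .containers import (
    AnalyticEpochs,
    ConnectivityTimeseries,
    SourceEpochs,
    WholeBrainTimeseries,
    window_mask,
)

__all__ = [
    "analytic_signal",
    "wpli_timeseries",
    "zscore_to_baseline",
    "mean_whole_brain",
    "window_average",
]


def analytic_signal(epochs: SourceEpochs) -> AnalyticEpochs:
    """Hilbert analytic signal per trial/region: x(t) + i H[x](t).

    The input should be narrowband filtered for the phase to be
    interpretable; the recorded band is carried over.
    """
    if not np.isfinite(epochs.data).all():
        raise ValueError("epoch data contain non-finite values")
    n = epochs.data.shape[-1]
    # zero-pad to a fast FFT length; the padding only perturbs the epoch
    # edges, which are cropped before analysis anyway
    z = hilbert(epochs.data, N=next_fast_len(n), axis=-1)[..., :n]
    return AnalyticEpochs(
        data=z,
        time=epochs.time,
        sampling_rate=epochs.sampling_rate,
        trial_labels=epochs.trial_labels,
        band=epochs.band,
        subject_id=epochs.subject_id,
        group=epochs.group,
        region_labels=epochs.region_labels,
    )


def wpli_timeseries(
    analytic: AnalyticEpochs,
    trials: np.ndarray | None = None,
    condition: str = "",
    debiased: bool = False,
) -> ConnectivityTimeseries:
    """Time-resolved wPLI between all region pairs, estimated across trials.

    Parameters
    ----------
    analytic
        Complex analytic epochs, ``(n_trials, N, n_samples)``.
    trials
        Optional trial subset (boolean mask or integer index).
    condition
        Label recorded on the output (provenance only).
    debiased
        If True, return the debiased squared estimator (can be negative).

    Returns a ``ConnectivityTimeseries`` with values ``(n_samples, N, N)``,
    symmetric with zero diagonal.
    """
    z = analytic.data if trials is None else analytic.data[np.asarray(trials)]
    n_trials, n_regions, n_samples = z.shape
    if n_trials < 2:
        raise ValueError(f"wPLI needs at least 2 trials, got {n_trials}")
    sum_im = np.zeros((n_regions, n_regions, n_samples))
    sum_abs = np.zeros_like(sum_im)
    if debiased:
        sum_sq = np.zeros_like(sum_im)
    # accumulate over trials to bound peak memory at O(N^2 T)
    for k in range(n_trials):
        cross_im = np.imag(z[k, :, None, :] * np.conj(z[k, None, :, :]))
        sum_im += cross_im
        sum_abs += np.abs(cross_im)
        if debiased:
            sum_sq += cross_im**2
    with np.errstate(divide="ignore", invalid="ignore"):
        if debiased:
            denom = sum_abs**2 - sum_sq
            w = (sum_im**2 - sum_sq) / denom
            w[denom == 0] = 0.0
        else:
            w = np.abs(sum_im) / sum_abs
            w[sum_abs == 0] = 0.0
    idx = np.arange(n_regions)
    w[idx, idx, :] = 0.0
    return ConnectivityTimeseries(
        values=np.moveaxis(w, -1, 0),
        time=analytic.time,
        band=analytic.band.name if analytic.band is not None else "",
        subject_id=analytic.subject_id,
        condition=condition,
        group=analytic.group,
        normalized=False,
        region_labels=analytic.region_labels,
    )


def zscore_to_baseline(
    conn: ConnectivityTimeseries,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
    ddof: int = 0,
) -> ConnectivityTimeseries:
    """Z-score each edge's timeseries to its own pre-stimulus baseline.

    For every edge, subtract the mean and divide by the SD of that edge's
    values over the baseline samples. The SD uses the population convention
    (``ddof=0``) by default; pass ``ddof=1`` for the sample convention. A
    zero baseline SD on any off-diagonal edge is an error (naming the edge).
    """
    if conn.normalized:
        raise ValueError("connectivity is already baseline-normalized")
    mask = window_mask(conn.time, baseline_ms)
    base = conn.values[mask]
    mean = base.mean(axis=0)
    sd = base.std(axis=0, ddof=ddof)
    n = conn.n_regions
    off = ~np.eye(n, dtype=bool)
    if np.any(sd[off] == 0.0):
        i, j = np.argwhere((sd == 0.0) & off)[0]
        raise ValueError(
            f"zero baseline SD on edge ({i}, {j}); cannot z-score a constant "
            "baseline timeseries"
        )
    sd_safe = np.where(sd == 0.0, 1.0, sd)  # diagonal only
    z = (conn.values - mean) / sd_safe
    idx = np.arange(n)
    z[:, idx, idx] = 0.0
    return replace(
        conn, values=z, normalized=True, baseline_window=tuple(baseline_ms)
    )


def mean_whole_brain(conn: ConnectivityTimeseries) -> WholeBrainTimeseries:
    """Mean over the N(N-1)/2 upper-triangle edges at each sample."""
    n = conn.n_regions
    iu = np.triu_indices(n, k=1)
    return WholeBrainTimeseries(
        values=conn.values[:, iu[0], iu[1]].mean(axis=1),
        time=conn.time,
        band=conn.band,
        subject_id=conn.subject_id,
        condition=conn.condition,
        group=conn.group,
        normalized=conn.normalized,
    )


def window_average(obj, window_ms: tuple[float, float]):
    """Arithmetic mean over samples with t in the half-open ms window.

    Returns an ``(N, N)`` edge matrix for a ``ConnectivityTimeseries`` and a
    scalar for a ``WholeBrainTimeseries``.
    """
    mask = window_mask(obj.time, window_ms)
    if isinstance(obj, ConnectivityTimeseries):
        return obj.values[mask].mean(axis=0)
    if isinstance(obj, WholeBrainTimeseries):
        return float(obj.values[mask].mean())
    raise TypeError(f"cannot window-average object of type {type(obj).__name__}")
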