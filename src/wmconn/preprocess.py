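"""Filtering, epoch cropping, and artifact-based trial screening.

The preprocessing chain mirrors a standard developmental-MEG pipeline:
broadband filter (1-150 Hz, 4th-order two-pass Butterworth) with a 60 Hz
power-line notch, narrowband filtering into analysis bands, and trial
rejection by head motion (> 10% of samples beyond 5 mm) or sensor amplitude
(> 2000 fT). Epochs are filtered whole and cropped afterwards so filter
transients fall outside the analysis window.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .containers import (
    AnalyticEpochs,
    ArtifactTraces,
    Band,
    ConnectivityTimeseries,
    ScreenReport,
    SourceEpochs,
    window_mask,
)

__all__ = [
    "broadband_filter",
    "band_filter",
    "screen_trials",
    "select_condition_trials",
    "crop",
]

#: Head-motion rejection: reject if more than this fraction of samples ...
MOTION_FRACTION = 0.10
#: ... exceeds this distance (mm) from the reference head position.
MOTION_THRESHOLD_MM = 5.0
#: Sensor-amplitude rejection threshold (fT).
AMPLITUDE_THRESHOLD_FT = 2000.0


def _design_bandpass(f_low: float, f_high: float, fs: float, order: int):
    if fs <= 2.0 * f_high:
        raise ValueError(
            f"band edge {f_high} Hz is at or above the Nyquist frequency {fs / 2} Hz"
        )
    return butter(order, (f_low, f_high), btype="bandpass", fs=fs, output="sos")


def _check_length(n_samples: int, sos: np.ndarray) -> None:
    # two-pass filtering needs settling room at both ends; require three
    # times the default reflective pad of sosfiltfilt
    settle = 2 * sos.shape[0] + 1
    min_len = 3 * settle + 1
    if n_samples < min_len:
        raise ValueError(
            f"epoch of {n_samples} samples is shorter than 3x the filter "
            f"settling length; at least {min_len} samples are required"
        )


def broadband_filter(
    epochs: SourceEpochs,
    f_low: float = 1.0,
    f_high: float = 150.0,
    notch_hz: float = 60.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> SourceEpochs:
    """Zero-phase broadband band-pass plus power-line notch, per trial/region.

    The band-pass is a 4th-order Butterworth applied forwards and backwards
    (two-pass, hence zero-phase); the notch is a 2nd-order IIR notch of
    quality factor ``notch_q`` applied the same way.
    """
    fs = epochs.sampling_rate
    sos = _design_bandpass(f_low, f_high, fs, order)
    _check_length(epochs.n_samples, sos)
    y = sosfiltfilt(sos, epochs.data, axis=-1)
    b, a = iirnotch(notch_hz, notch_q, fs=fs)
    y = filtfilt(b, a, y, axis=-1)
    return replace(epochs, data=y)


def band_filter(epochs: SourceEpochs, band: Band, order: int = 4) -> SourceEpochs:
    """Zero-phase 4th-order Butterworth band-pass into ``band``; records the band."""
    sos = _design_bandpass(band.f_low, band.f_high, epochs.sampling_rate, order)
    _check_length(epochs.n_samples, sos)
    y = sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=y, band=band)


def screen_trials(
    traces: ArtifactTraces,
    epochs: SourceEpochs | None = None,
    motion_threshold_mm: float = MOTION_THRESHOLD_MM,
    motion_fraction: float = MOTION_FRACTION,
    amplitude_threshold_ft: float = AMPLITUDE_THRESHOLD_FT,
) -> ScreenReport:
    """Flag trials for rejection by head motion or sensor amplitude.

    A trial is rejected iff strictly more than ``motion_fraction`` of its
    head-position samples exceed ``motion_threshold_mm`` (strictly), or any
    channel's peak absolute amplitude strictly exceeds
    ``amplitude_threshold_ft``. Motion takes precedence in the recorded
    reason when both rules fire. Boundary values (exactly 10% of samples,
    exactly 2000 fT) are kept.
    """
    if epochs is not None and epochs.n_trials != traces.n_trials:
        raise ValueError(
            f"trial-count mismatch: epochs have {epochs.n_trials} trials, "
            f"traces have {traces.n_trials}"
        )
    frac = np.mean(traces.head_position > motion_threshold_mm, axis=1)
    motion_rej = frac > motion_fraction
    amp_rej = np.any(traces.peak_amplitude > amplitude_threshold_ft, axis=1)
    keep = ~(motion_rej | amp_rej)
    reason = np.where(motion_rej, "motion", np.where(amp_rej, "amplitude", "none"))
    return ScreenReport(
        keep=keep,
        reason=reason.astype(object),
        motion_threshold_mm=motion_threshold_mm,
        motion_fraction=motion_fraction,
        amplitude_threshold_ft=amplitude_threshold_ft,
    )


def select_condition_trials(epochs: SourceEpochs, condition: str) -> SourceEpochs:
    """Subset the epochs to trials of one condition, preserving trial order."""
    mask = epochs.trial_labels == condition
    if not mask.any():
        counts = {
            str(lbl): int(n)
            for lbl, n in zip(*np.unique(epochs.trial_labels, return_counts=True))
        }
        raise ValueError(
            f"no trials with condition {condition!r}; available counts: {counts}"
        )
    return epochs.select_trials(mask)


def crop(obj, window_ms: tuple[float, float]):
    """Restrict epochs/analytic/connectivity objects to a half-open ms window.

    Filtering and the Hilbert transform are applied to the full epoch; the
    analysis then uses only the interior (default elsewhere: -500..1250 ms)
    so that edge transients are discarded.
    """
    mask = window_mask(obj.time, window_ms)
    if isinstance(obj, (SourceEpochs, AnalyticEpochs)):
        return replace(obj, data=obj.data[:, :, mask], time=obj.time[mask])
    if isinstance(obj, ConnectivityTimeseries):
        return replace(obj, values=obj.values[mask], time=obj.time[mask])
    raise TypeError(f"cannot crop object of type {type(obj).__name__}")
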