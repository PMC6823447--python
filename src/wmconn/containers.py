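"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* epoch data arrays are ``(n_trials, n_regions, n_samples)``, time in seconds
  with 0 = stimulus onset;
* analysis windows are millisecond pairs interpreted half-open,
  ``[start, end)``;
* connectivity arrays are ``(n_samples, n_regions, n_regions)``, symmetric
  with a zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Band",
    "DEFAULT_BANDS",
    "SourceEpochs",
    "AnalyticEpochs",
    "ConnectivityTimeseries",
    "WholeBrainTimeseries",
    "ArtifactTraces",
    "ScreenReport",
    "window_mask",
]


@dataclass(frozen=True)
class Band:
    """A frequency band with inclusive pass edges in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.f_high - self.f_low)


#: Canonical working-memory analysis bands.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("theta", 4.0, 7.0),
    Band("alpha", 8.0, 14.0),
    Band("beta", 15.0, 30.0),
    Band("low_gamma", 30.0, 55.0),
)


def window_mask(time_s: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    """Boolean mask of samples with time in the half-open window [start, end) ms.

    A 1 ns tolerance absorbs floating-point jitter on the time axis.
    Raises if the window selects no samples.
    """
    start, end = window_ms
    if not end > start:
        raise ValueError(f"empty window: ({start}, {end}) ms")
    t_ms = np.asarray(time_s, dtype=float) * 1000.0
    mask = (t_ms >= start - 1e-6) & (t_ms < end - 1e-6)
    if not mask.any():
        raise ValueError(
            f"window [{start}, {end}) ms selects no samples on a time axis "
            f"spanning [{t_ms[0]:.1f}, {t_ms[-1]:.1f}] ms"
        )
    return mask


def _default_region_labels(n: int) -> tuple[str, ...]:
    from .atlas import AAL90_LABELS

    if n == len(AAL90_LABELS):
        return AAL90_LABELS
    return tuple(f"ROI_{i:03d}" for i in range(n))


@dataclass
class SourceEpochs:
    """Per-subject epoched source-space timeseries.

    ``data`` is real, shaped ``(n_trials, n_regions, n_samples)``; ``time``
    is in seconds with 0 at stimulus onset. ``band`` is set once the data
    have been narrowband filtered.
    """

    data: np.ndarray
    time: np.ndarray
    sampling_rate: float
    trial_labels: np.ndarray
    subject_id: str = "S000"
    group: str = ""
    region_labels: tuple[str, ...] | None = None
    band: Band | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.trial_labels = np.asarray(self.trial_labels)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (trials, regions, samples), got {self.data.shape}")
        if self.time.shape != (self.data.shape[2],):
            raise ValueError("time axis length does not match the sample axis")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time axis must be strictly increasing")
        if len(self.trial_labels) != self.data.shape[0]:
            raise ValueError("one trial label per trial required")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contain non-finite values")
        if self.region_labels is None:
            self.region_labels = _default_region_labels(self.data.shape[1])
        elif len(self.region_labels) != self.data.shape[1]:
            raise ValueError("one region label per region required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, index: np.ndarray) -> "SourceEpochs":
        """Subset trials (boolean mask or integer index), preserving order."""
        index = np.asarray(index)
        return replace(
            self,
            data=self.data[index],
            trial_labels=self.trial_labels[index],
        )


@dataclass
class AnalyticEpochs:
    """Complex analytic signal per trial/region; phase = angle, amplitude = modulus."""

    data: np.ndarray
    time: np.ndarray
    sampling_rate: float
    trial_labels: np.ndarray
    band: Band | None = None
    subject_id: str = "S000"
    group: str = ""
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.time = np.asarray(self.time, dtype=float)
        self.trial_labels = np.asarray(self.trial_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials, regions, samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("analytic data contain non-finite values")
        if self.region_labels is None:
            self.region_labels = _default_region_labels(self.data.shape[1])

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityTimeseries:
    """Time-resolved symmetric connectivity, ``values[(t, i, j)]``.

    Raw wPLI values lie in [0, 1]; once z-scored to the pre-stimulus
    baseline (``normalized=True``) they are unbounded.
    """

    values: np.ndarray
    time: np.ndarray
    band: str = ""
    subject_id: str = "S000"
    condition: str = ""
    group: str = ""
    normalized: bool = False
    baseline_window: tuple[float, float] | None = None
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (samples, N, N)")
        if self.values.shape[0] != self.time.shape[0]:
            raise ValueError("time axis length does not match the sample axis")
        if self.region_labels is None:
            self.region_labels = _default_region_labels(self.values.shape[1])

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def validate(self) -> None:
        """Assert the structural invariants (used in tests; O(T N^2))."""
        v = self.values
        if not np.isfinite(v).all():
            raise AssertionError("non-finite connectivity values")
        if not np.allclose(v, np.swapaxes(v, 1, 2)):
            raise AssertionError("connectivity matrices are not symmetric")
        diag = np.einsum("tii->ti", v)
        if not np.allclose(diag, 0.0):
            raise AssertionError("connectivity diagonal is not zero")
        if not self.normalized and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
            raise AssertionError("raw wPLI outside [0, 1]")


@dataclass
class WholeBrainTimeseries:
    """Mean over the N(N-1)/2 region pairs at each sample."""

    values: np.ndarray
    time: np.ndarray
    band: str = ""
    subject_id: str = "S000"
    condition: str = ""
    group: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.values.shape != self.time.shape:
            raise ValueError("values and time must be 1-D and aligned")


@dataclass
class ArtifactTraces:
    """Per-trial screening traces emulating head-position and sensor peaks.

    ``head_position`` is the distance (mm) from the reference head position
    per trial per sample; ``peak_amplitude`` is each channel's maximum
    absolute signal per trial (fT). The ``*_contaminated`` arrays are the
    generator's ground-truth labels when the traces are synthetic.
    """

    head_position: np.ndarray
    peak_amplitude: np.ndarray
    motion_contaminated: np.ndarray | None = None
    spike_contaminated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.head_position = np.asarray(self.head_position, dtype=float)
        self.peak_amplitude = np.asarray(self.peak_amplitude, dtype=float)
        if self.head_position.ndim != 2 or self.peak_amplitude.ndim != 2:
            raise ValueError("head_position and peak_amplitude must be 2-D")
        if self.head_position.shape[0] != self.peak_amplitude.shape[0]:
            raise ValueError("trial counts of the two traces disagree")
        if (self.head_position < 0).any():
            raise ValueError("head-position distances must be >= 0")

    @property
    def n_trials(self) -> int:
        return self.head_position.shape[0]


@dataclass
class ScreenReport:
    """Outcome of trial screening: keep flag and rejection reason per trial."""

    keep: np.ndarray
    reason: np.ndarray  # 'motion' | 'amplitude' | 'none'
    motion_threshold_mm: float
    motion_fraction: float
    amplitude_threshold_ft: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.reason = np.asarray(self.reason, dtype=object)
        if self.keep.shape != self.reason.shape:
            raise ValueError("keep and reason must align")
        if any((k and r != "none") or (not k and r == "none")
               for k, r in zip(self.keep, self.reason)):
            raise ValueError("rejection reasons inconsistent with keep flags")

    @property
    def n_total(self) -> int:
        return self.keep.size

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def n_rejected(self) -> int:
        return self.n_total - self.n_kept

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"trial": np.arange(self.n_total), "keep": self.keep, "reason": self.reason}
        )
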