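"""High-level chains tying the pipeline stages together.

These helpers express the canonical analysis path — screen trials, select
a condition, filter, Hilbert, wPLI, crop, baseline z-score — as single
calls, shared by the CLI, the tests and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import connectivity, preprocess
from .containers import ArtifactTraces, Band, ConnectivityTimeseries, SourceEpochs

__all__ = ["subject_connectivity", "ANALYSIS_WINDOW_MS"]

#: Interior analysis window; the -1..2 s epoch is filtered whole and then
#: truncated to this range so filter/Hilbert transients are discarded.
ANALYSIS_WINDOW_MS = (-500.0, 1250.0)


def subject_connectivity(
    epochs: SourceEpochs,
    band: Band,
    condition: str | None = None,
    traces: ArtifactTraces | None = None,
    broadband: bool = True,
    crop_ms: tuple[float, float] = ANALYSIS_WINDOW_MS,
    zscore: bool = True,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
) -> ConnectivityTimeseries:
    """Full single-subject chain from raw epochs to (normalized) wPLI.

    Steps: optional artifact screening, optional condition selection,
    broadband + band filtering, Hilbert transform, time-resolved wPLI,
    truncation to the analysis window, and baseline z-scoring.
    """
    if traces is not None:
        report = preprocess.screen_trials(traces, epochs)
        epochs = epochs.select_trials(report.keep)
        if traces.head_position.shape[0] != report.keep.size:
            raise AssertionError  # unreachable; screen_trials validated alignment
    if condition is not None:
        epochs = preprocess.select_condition_trials(epochs, condition)
    if broadband:
        epochs = preprocess.broadband_filter(epochs)
    epochs = preprocess.band_filter(epochs, band)
    analytic = connectivity.analytic_signal(epochs)
    analytic = preprocess.crop(analytic, crop_ms)
    conn = connectivity.wpli_timeseries(analytic, condition=condition or "")
    if zscore:
        conn = connectivity.zscore_to_baseline(conn, baseline_ms)
    return conn
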