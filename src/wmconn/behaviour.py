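"""Demographic/behavioural group statistics and brain-behaviour correlations.

Implements the summary-level inferential statistics used to characterize a
two-group cohort (pooled-variance two-sample t-tests from printed
mean/SD/n summaries, Pearson chi-square tests on category counts) and the
correlation of retention-interval whole-brain connectivity with task
accuracy. Printed t-values with df = n1 + n2 - 2 imply the pooled-variance
(not Welch) convention, which is what ``pooled_t_from_summary`` computes;
the chi-square is Pearson's without continuity correction (with Yates'
correction the canonical 2x2 sex-distribution check would not reproduce).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import mean_whole_brain, window_average
from .containers import ConnectivityTimeseries

__all__ = [
    "pooled_t_from_summary",
    "pooled_t_from_data",
    "chi_square",
    "pearson_correlation",
    "brain_behaviour",
]


def pooled_t_from_summary(
    n1: int, m1: float, s1: float, n2: int, m2: float, s2: float
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from group summaries.

    Returns ``(t, df, p)`` with ``df = n1 + n2 - 2`` and a two-sided p from
    the t distribution. Zero pooled variance with unequal means yields an
    infinite t (flagged with a warning).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    diff = m1 - m2
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means: t is infinite")
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def pooled_t_from_data(x, y) -> tuple[float, int, float]:
    """Pooled two-sample t from raw data; cross-check for the summary route."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pooled_t_from_summary(
        x.size, x.mean(), x.std(ddof=1), y.size, y.mean(), y.std(ddof=1)
    )


def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table, without continuity correction.

    Returns ``(chi2, df, p)`` with ``df = (r-1)(c-1)``. All expected counts
    must be positive (zero marginals are rejected).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("table must be 2-D")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal; chi-square undefined")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("all expected counts must be > 0")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p via t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def brain_behaviour(
    subject_conns: dict,
    table: pd.DataFrame,
    window_ms: tuple[float, float] = (250.0, 1250.0),
) -> dict:
    """Correlate retention-interval whole-brain connectivity with accuracy.

    Parameters
    ----------
    subject_conns
        ``subject_id -> ConnectivityTimeseries`` (baseline-normalized,
        correct trials only).
    table
        Behaviour table with ``subject_id``, ``group`` and ``accuracy``
        columns.
    window_ms
        Averaging window (default: the 1 s retention interval).

    Returns ``group -> {r, p, n}`` using, per subject, the whole-brain mean
    of the window-averaged normalized connectivity.
    """
    scores = {}
    for sid, conn in subject_conns.items():
        if not conn.normalized:
            raise ValueError(f"connectivity for {sid} is not baseline-normalized")
        scores[sid] = window_average(mean_whole_brain(conn), window_ms)
    out = {}
    for group, sub in table.groupby("group", sort=True):
        sub = sub[sub["subject_id"].isin(scores)]
        if len(sub) == 0:
            continue
        if len(sub) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 subjects with connectivity")
        x = np.array([scores[sid] for sid in sub["subject_id"]])
        y = sub["accuracy"].to_numpy(dtype=float)
        r, p = pearson_correlation(x, y)
        out[group] = {"r": r, "p": p, "n": int(len(sub))}
    return out
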