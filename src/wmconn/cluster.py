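"""Supra-threshold-window permutation test for connectivity timeseries.

Compares two sets of whole-brain connectivity timeseries sample by sample
with a t-statistic, finds maximal runs of consecutive samples whose t
exceeds a fixed threshold (default t > 1.7, one-sided), and corrects for
multiple comparisons over time by permutation: on each permutation the
condition labels are exchanged (paired: independent per-subject swaps,
equivalent to sign-flipping the difference; unpaired: group-label
shuffles), the t-vector recomputed, and the length of the largest
supra-threshold run recorded into the null distribution. An observed run
is significant when it is strictly longer than the 95th percentile of that
null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import WholeBrainTimeseries

__all__ = ["ClusterTestResult", "timepoint_tstats", "cluster_permutation_test", "stack_series"]


def stack_series(series: list[WholeBrainTimeseries]) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject whole-brain timeseries into (n_subjects, T) + time."""
    if not series:
        raise ValueError("no timeseries given")
    time = series[0].time
    for s in series[1:]:
        if s.values.shape != time.shape or not np.allclose(s.time, time):
            raise ValueError("timeseries have inconsistent time axes")
    return np.stack([s.values for s in series]), time


def _as_array(series) -> np.ndarray:
    if isinstance(series, np.ndarray):
        arr = np.atleast_2d(np.asarray(series, dtype=float))
    else:
        arr, _ = stack_series(list(series))
    return arr


def _one_sample_t(d: np.ndarray) -> np.ndarray:
    """Per-column one-sample t of (n, T) differences; zero variance -> t = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t[~np.isfinite(t)] = 0.0
    return t


def timepoint_tstats(series_a, series_b, paired: bool = True) -> np.ndarray:
    """Per-sample t-statistic between two timeseries sets.

    ``paired=True`` computes a one-sample t on per-subject differences
    (subjects must align); ``paired=False`` a pooled two-sample t. A sample
    with zero variance yields t = 0 by convention.
    """
    a, b = _as_array(series_a), _as_array(series_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per side")
    if a.shape[1] != b.shape[1]:
        raise ValueError("timeseries lengths differ")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test requires equal subject counts, in order")
        return _one_sample_t(a - b)
    return _pooled_t(a, b)


def _runs(supra: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) sample pairs, stop exclusive."""
    padded = np.diff(np.concatenate(([0], supra.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _max_run_lengths(supra_rows: np.ndarray) -> np.ndarray:
    """Largest run length of True per row of a (m, T) boolean array."""
    m, T = supra_rows.shape
    out = np.zeros(m, dtype=int)
    for i in range(m):
        runs = _runs(supra_rows[i])
        if runs:
            out[i] = max(stop - start for start, stop in runs)
    return out


@dataclass
class ClusterTestResult:
    """Observed supra-threshold windows with their max-run-length null."""

    t_observed: np.ndarray
    clusters: list  # dicts: start/stop sample, length, p, significant, ms bounds
    null_distribution: np.ndarray
    critical_length: float
    params: dict
    warnings: list = field(default_factory=list)

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c["significant"]]

    def to_dict(self) -> dict:
        return {
            "clusters": self.clusters,
            "critical_length": float(self.critical_length),
            "n_significant": len(self.significant_clusters),
            "params": self.params,
            "warnings": self.warnings,
        }


def cluster_permutation_test(
    series_a,
    series_b,
    n_perm: int = 1000,
    t_threshold: float = 1.7,
    alpha: float = 0.05,
    paired: bool = True,
    two_sided: bool = False,
    seed: int | None = None,
    time: np.ndarray | None = None,
) -> ClusterTestResult:
    """Supra-threshold-window permutation test between two timeseries sets.

    Observed clusters are maximal runs of consecutive samples with
    ``t > t_threshold`` (strict; ``two_sided=True`` thresholds ``|t|``). A
    cluster is significant iff its length strictly exceeds the
    ``100*(1-alpha)`` percentile (linear interpolation) of the permutation
    null of largest run lengths; ties at the critical value are
    non-significant. Per-cluster p-values use the exceedance convention
    ``p = (1 + #{null >= length}) / (1 + n_perm)``. Deterministic given
    ``seed``.
    """
    if isinstance(series_a, list) and series_a and isinstance(series_a[0], WholeBrainTimeseries):
        _, time_axis = stack_series(series_a)
    else:
        time_axis = time
    a, b = _as_array(series_a), _as_array(series_b)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    warns: list[str] = []
    if 1.0 / n_perm > alpha:
        warns.append(
            f"n_perm={n_perm} cannot resolve alpha={alpha}: smallest attainable "
            f"p is {1.0 / n_perm:.4g}"
        )
    rng = np.random.default_rng(seed)

    t_obs = timepoint_tstats(a, b, paired=paired)
    stat = np.abs(t_obs) if two_sided else t_obs
    observed_runs = _runs(stat > t_threshold)

    T = a.shape[1]
    if paired:
        d = a - b
        n = d.shape[0]
        signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
        m = signs @ d / n
        ssq = (d**2).sum(axis=0)  # invariant under sign flips
        var = (ssq - n * m**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = m / np.sqrt(var / n)
        t_null[~np.isfinite(t_null)] = 0.0
    else:
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        t_null = np.empty((n_perm, T))
        for p in range(n_perm):
            order = rng.permutation(pooled.shape[0])
            t_null[p] = _pooled_t(pooled[order[:na]], pooled[order[na:]])
    stat_null = np.abs(t_null) if two_sided else t_null
    null = _max_run_lengths(stat_null > t_threshold)

    critical = float(np.percentile(null, 100.0 * (1.0 - alpha)))
    clusters = []
    for start, stop in observed_runs:
        length = stop - start
        p_val = (1 + int((null >= length).sum())) / (1 + n_perm)
        c = {
            "start_sample": int(start),
            "stop_sample": int(stop),
            "length": int(length),
            "p": float(p_val),
            "significant": bool(length > critical),
        }
        if time_axis is not None:
            c["start_ms"] = float(time_axis[start] * 1000.0)
            c["stop_ms"] = float(time_axis[stop - 1] * 1000.0)
        clusters.append(c)
    clusters.sort(key=lambda c: c["p"])
    return ClusterTestResult(
        t_observed=t_obs,
        clusters=clusters,
        null_distribution=null,
        critical_length=critical,
        params={
            "n_perm": n_perm,
            "t_threshold": t_threshold,
            "alpha": alpha,
            "paired": paired,
            "two_sided": two_sided,
            "seed": seed,
        },
        warnings=warns,
    )
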