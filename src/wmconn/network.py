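"""Network-Based Statistic, hub analysis, and masked network-sum tests.

The NBS contrasts baseline-normalized connectivity between two task windows
(retention vs. pre-stimulus baseline) edge by edge with a paired t-test
across subjects, thresholds the t-matrix (default t > 2.0, one-sided), and
identifies connected components of supra-threshold edges. Family-wise
error is controlled at the component level: each permutation sign-flips
the per-subject window difference (the two windows are within-subject
measures), recomputes the full t-matrix, and records the maximal component
size; a component's corrected p-value is the exceedance rate of its size
against that null.

Hubs are identified by node degree (the number of edges a node has within
a component). Between-group comparisons use the sum of network
connectivity: all connections outside a mask (typically a significant
within-group component) are discarded and the remaining window-averaged
z-scored wPLI values are summed per subject, giving one value per subject
for a group-label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectivity import window_average
from .containers import ConnectivityTimeseries

__all__ = [
    "EdgeContrast",
    "NetworkComponent",
    "NBSResult",
    "NetworkSumResult",
    "edge_contrast",
    "connected_components",
    "nbs",
    "node_degree",
    "network_sum",
    "group_permutation_test",
]


RETENTION_MS = (250.0, 1250.0)
BASELINE_MS = (-500.0, 0.0)


@dataclass
class EdgeContrast:
    """Edge-wise paired t-matrix between two windows, plus the per-subject
    window differences it was computed from (needed for permutation)."""

    t_matrix: np.ndarray
    subject_diffs: np.ndarray  # (n_subjects, N, N)
    window_a: tuple[float, float]
    window_b: tuple[float, float]
    warnings: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.t_matrix.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.subject_diffs.shape[0]


@dataclass
class NetworkComponent:
    """A connected set of supra-threshold edges."""

    edges: list  # [(i, j), ...] with i < j
    p_corrected: float | None = None

    def __post_init__(self) -> None:
        self.edges = sorted((min(i, j), max(i, j)) for i, j in self.edges)

    @property
    def nodes(self) -> list:
        return sorted({v for e in self.edges for v in e})

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def node_degree(self) -> dict:
        deg: dict[int, int] = {}
        for i, j in self.edges:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
        return deg


@dataclass
class NBSResult:
    components: list  # NetworkComponent, sorted by size descending
    t_matrix: np.ndarray
    null_max_size: np.ndarray
    params: dict
    warnings: list = field(default_factory=list)

    @property
    def significant_components(self) -> list:
        alpha = self.params["alpha"]
        return [c for c in self.components if c.p_corrected is not None
                and c.p_corrected <= alpha]


@dataclass
class NetworkSumResult:
    values_a: np.ndarray
    values_b: np.ndarray
    observed_difference: float
    p: float
    null_distribution: np.ndarray
    params: dict

    def to_dict(self) -> dict:
        return {
            "observed_difference": float(self.observed_difference),
            "p": float(self.p),
            "n_a": int(self.values_a.size),
            "n_b": int(self.values_b.size),
            "params": self.params,
        }


def _window_means(
    subject_conns: list[ConnectivityTimeseries], window_ms
) -> np.ndarray:
    return np.stack([window_average(c, window_ms) for c in subject_conns])


def edge_contrast(
    subject_conns: list[ConnectivityTimeseries],
    window_a: tuple[float, float] = RETENTION_MS,
    window_b: tuple[float, float] = BASELINE_MS,
) -> EdgeContrast:
    """Paired t across subjects of each edge's (window_a - window_b) mean.

    Expects baseline-normalized connectivity (one object per subject).
    Zero-variance edges yield t = 0 with a warning.
    """
    if len(subject_conns) < 3:
        raise ValueError("need at least 3 subjects for an edge contrast")
    diffs = _window_means(subject_conns, window_a) - _window_means(subject_conns, window_b)
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    warns = []
    n_regions = diffs.shape[1]
    off = ~np.eye(n_regions, dtype=bool)
    if np.any(sd[off] == 0.0):
        warns.append("zero-variance edge(s); t set to 0 there")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    idx = np.arange(n_regions)
    t[idx, idx] = 0.0
    return EdgeContrast(
        t_matrix=t,
        subject_diffs=diffs,
        window_a=tuple(window_a),
        window_b=tuple(window_b),
        warnings=warns,
    )


def connected_components(supra_adj: np.ndarray) -> list[NetworkComponent]:
    """Connected components (without p-values) of a thresholded adjacency.

    ``supra_adj`` is a symmetric boolean/0-1 matrix with zero diagonal whose
    nonzero entries are the supra-threshold edges. Component size is
    measured in edges; isolated nodes form no component.
    """
    adj = np.asarray(supra_adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(adj)):
        raise ValueError("adjacency diagonal must be zero")
    g = nx.Graph()
    iu = np.triu_indices(adj.shape[0], k=1)
    edges = [(int(i), int(j)) for i, j in zip(*iu) if adj[i, j]]
    g.add_edges_from(edges)
    comps = [
        NetworkComponent(edges=list(g.subgraph(nodes).edges()))
        for nodes in nx.connected_components(g)
    ]
    comps.sort(key=lambda c: (-c.n_edges, c.edges))
    return comps


def _t_from_diffs_flat(diffs_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized per-permutation paired t over flattened edges.

    ``diffs_flat``: (S, E); ``signs``: (P, S) of +-1. Returns (P, E).
    Uses the identity that the sum of squares is sign-invariant.
    """
    S = diffs_flat.shape[0]
    m = signs @ diffs_flat / S
    ssq = (diffs_flat**2).sum(axis=0)
    var = (ssq - S * m**2) / (S - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / S)
    t[~np.isfinite(t)] = 0.0
    return t


def nbs(
    subject_conns: list[ConnectivityTimeseries],
    window_a: tuple[float, float] = RETENTION_MS,
    window_b: tuple[float, float] = BASELINE_MS,
    t_threshold: float = 2.0,
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    two_sided: bool = False,
    component_size: str = "edges",
) -> NBSResult:
    """Network-Based Statistic for a within-subject window contrast.

    Observed components come from ``edge_contrast`` thresholded at
    ``t > t_threshold`` (strict, one-sided by default). Each permutation
    applies independent per-subject window-label swaps (sign flips of the
    per-subject difference), recomputes the full t-matrix, thresholds it,
    and records the maximal component size. ``p_corrected(component) =
    (1 + #{null max-size >= size}) / (1 + n_perm)``. Deterministic given
    ``seed``.
    """
    if component_size not in ("edges", "nodes"):
        raise ValueError("component_size must be 'edges' or 'nodes'")
    contrast = edge_contrast(subject_conns, window_a, window_b)
    warns = list(contrast.warnings)
    if n_perm < 1.0 / alpha:
        warns.append(
            f"n_perm={n_perm} cannot resolve alpha={alpha}: smallest attainable "
            f"corrected p is {1.0 / (1 + n_perm):.4g}"
        )
    n_regions = contrast.n_regions

    def _size(c: NetworkComponent) -> int:
        return c.n_edges if component_size == "edges" else c.n_nodes

    def _threshold(t_mat: np.ndarray) -> np.ndarray:
        stat = np.abs(t_mat) if two_sided else t_mat
        return stat > t_threshold

    observed = connected_components(_threshold(contrast.t_matrix))

    rng = np.random.default_rng(seed)
    S = contrast.n_subjects
    iu = np.triu_indices(n_regions, k=1)
    diffs_flat = contrast.subject_diffs[:, iu[0], iu[1]]
    signs = rng.integers(0, 2, size=(n_perm, S)) * 2 - 1
    t_null = _t_from_diffs_flat(diffs_flat, signs)
    stat_null = np.abs(t_null) if two_sided else t_null
    supra_null = stat_null > t_threshold

    null_max = np.zeros(n_perm, dtype=int)
    adj = np.zeros((n_regions, n_regions), dtype=bool)
    for p in range(n_perm):
        hits = supra_null[p]
        if not hits.any():
            continue
        adj[:] = False
        adj[iu[0][hits], iu[1][hits]] = True
        adj |= adj.T
        comps = connected_components(adj)
        null_max[p] = max(_size(c) for c in comps)

    for comp in observed:
        size = _size(comp)
        comp.p_corrected = (1 + int((null_max >= size).sum())) / (1 + n_perm)
    return NBSResult(
        components=observed,
        t_matrix=contrast.t_matrix,
        null_max_size=null_max,
        params={
            "window_a": tuple(window_a),
            "window_b": tuple(window_b),
            "t_threshold": t_threshold,
            "n_perm": n_perm,
            "alpha": alpha,
            "seed": seed,
            "two_sided": two_sided,
            "component_size": component_size,
        },
        warnings=warns,
    )


def node_degree(component: NetworkComponent) -> list:
    """Degrees ranked descending; ties broken by ascending node index."""
    deg = component.node_degree
    return sorted(deg.items(), key=lambda kv: (-kv[1], kv[0]))


def network_sum(
    subject_conn: ConnectivityTimeseries,
    mask_edges,
    window_ms: tuple[float, float] = RETENTION_MS,
) -> float:
    """Sum of window-averaged connectivity over the masked edge set.

    All connections outside ``mask_edges`` are ignored; the result is a
    single value per subject quantifying how strongly that subject recruits
    the network. Expects baseline-normalized connectivity.
    """
    edges = [(min(i, j), max(i, j)) for i, j in mask_edges]
    if not edges:
        raise ValueError("mask contains no edges")
    n = subject_conn.n_regions
    for i, j in edges:
        if not (0 <= i < j < n):
            raise ValueError(f"mask edge ({i}, {j}) invalid for {n} regions")
    wa = window_average(subject_conn, window_ms)
    return float(sum(wa[i, j] for i, j in edges))


def group_permutation_test(
    values_a,
    values_b,
    n_perm: int = 5000,
    seed: int | None = None,
) -> NetworkSumResult:
    """Two-sided permutation test on the difference of group means.

    The null is built by shuffling group labels over the pooled per-subject
    values; ``p = (1 + #{|null| >= |observed|}) / (1 + n_perm)``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 subjects")
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        order = rng.permutation(pooled.size)
        null[p] = pooled[order[: a.size]].mean() - pooled[order[a.size :]].mean()
    p_val = (1 + int((np.abs(null) >= abs(observed)).sum())) / (1 + n_perm)
    return NetworkSumResult(
        values_a=a,
        values_b=b,
        observed_difference=float(observed),
        p=float(p_val),
        null_distribution=null,
        params={"n_perm": n_perm, "seed": seed},
    )
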