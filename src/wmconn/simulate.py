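"""Coupled-oscillator cohort simulator with planted phase-coupled networks.

The generator emulates the data model of a beamformed MEG working-memory
experiment: per-subject epoched source-space timeseries (trials x regions x
samples), two birth-status groups, correct/incorrect trial labels, task
windows (pre-stimulus baseline, encoding, retention), artifact-screening
traces, and a behaviour table — together with a ``SimulationTruth`` record
sufficient to regenerate any subject bit-exactly and to score every
downstream inference against ground truth.

Signal model
------------
Each region's trial signal is a sum over frequency bands of a narrowband
oscillation ``A_b * cos(phi(t))`` plus white noise. The band phase is an
*integrated bounded-drift random walk*: the instantaneous frequency is an
Ornstein-Uhlenbeck process around the band centre, clipped to stay inside
the band, so that uncoupled regions decorrelate (the wPLI of deterministic
equal-frequency sinusoids would be degenerate).

Phase coupling on a planted edge set is implemented in phase, because the
weighted phase lag index is blind to zero-lag (volume-conduction-like)
coupling. Coupling strength ``kappa`` acts as a trial-level mixture: on
each trial the network is *coupled* with probability ``kappa`` and fully
independent otherwise. On a coupled trial every node of the planted
component follows a shared component phase plus a per-node lag,

    phi_node(t) = gate(t) * (phi_common(t) + lag_node)
                  + (1 - gate(t)) * phi_indep(t),

where ``gate`` is a 0/1 window indicator with 50 ms cosine ramps (abrupt
phase-regime switches would create broadband transients). Across trials
the phase-difference distribution on a planted edge is therefore a
kappa : (1-kappa) mixture of a constant-lag point mass and a circular-
uniform component, so the downstream wPLI responds monotonically and
almost linearly in kappa. Per-node lags are resampled until every planted
edge has a lag difference of magnitude in [0.8, 2.4] rad, excluding the
wPLI-blind neighbourhoods of 0 and pi. At ``kappa = 0`` phases are fully
independent; at ``kappa = 1`` coupled nodes are exact lagged copies of the
common phase on every trial.

Each *connected component* of a planted edge set gets its own common
phase process, so disjoint planted structures stay mutually independent.
Within a connected component, sharing one common phase synchronizes every
node pair, not only the listed edges: the ground-truth synchronized edge
set is the within-component pair closure, reported as
``closure_edges``/``synchrony_closure`` and the appropriate reference for
scoring network recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import (
    DEFAULT_BANDS,
    ArtifactTraces,
    Band,
    SourceEpochs,
    window_mask,
)

__all__ = [
    "GroupSpec",
    "PlantedNetwork",
    "BehaviourLink",
    "SimulationConfig",
    "SimulationTruth",
    "Cohort",
    "make_cohort",
    "make_behaviour_table",
    "make_artifact_traces",
    "desk_scale_config",
]

# Oscillator constants (rad / Hz / s); see docs/methods.md for rationale.
TAU_FREQ_DRIFT_S = 0.05    # correlation time of the instantaneous-frequency drift
FREQ_DRIFT_FRACTION = 0.15  # stationary SD of the drift, as fraction of band half-width
FREQ_DRIFT_CLIP = 0.9      # drift clipped to +- this fraction of the half-width
RAMP_MS = 50.0             # cosine ramp at coupling-window edges
LAG_MIN_RAD = 0.8          # minimum |lag difference| on a planted edge
LAG_MAX_RAD = 2.4          # maximum |lag difference| (stays clear of pi)
_NODE_LAG_RANGE = 1.2      # per-node lags drawn uniform in +- this range

# Seed-stream tags: SeedSequence entropy is (master_seed, tag, *counters).
_TAG_SUBJECT = 101
_TAG_TRIAL = 202
_TAG_ARTIFACT = 303
_TAG_BEHAVIOUR = 404


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_subjects: int


@dataclass(frozen=True)
class PlantedNetwork:
    """A ground-truth coupled edge set, active in one window/group/condition.

    ``window`` is a task-window name or an explicit ms pair; ``group`` /
    ``condition`` of ``None`` mean "all".
    """

    band: str
    edges: tuple[tuple[int, int], ...]
    kappa: float
    window: str | tuple[float, float] = "retention"
    group: str | None = None
    condition: str | None = "correct"

    @property
    def nodes(self) -> tuple[int, ...]:
        return tuple(sorted({v for e in self.edges for v in e}))

    @property
    def components(self) -> tuple[tuple[int, ...], ...]:
        """Node sets of the connected components of the planted edge set."""
        import networkx as nx

        g = nx.Graph(list(self.edges))
        return tuple(tuple(sorted(c)) for c in sorted(nx.connected_components(g), key=min))

    @property
    def synchrony_closure(self) -> tuple[tuple[int, int], ...]:
        """All node pairs synchronized by the common-phase construction:
        the within-component pair closure of the planted edges."""
        pairs = set()
        for comp in self.components:
            for a_idx in range(len(comp)):
                for b_idx in range(a_idx + 1, len(comp)):
                    pairs.add((comp[a_idx], comp[b_idx]))
        return tuple(sorted(pairs))


@dataclass(frozen=True)
class BehaviourLink:
    """Linear link from realized coupling to task accuracy (%)."""

    intercept: float = 80.0
    slope: float = 0.0
    noise_sd: float = 5.0


@dataclass
class SimulationConfig:
    n_regions: int = 90
    sampling_rate: float = 600.0
    epoch_window: tuple[float, float] = (-1.0, 2.0)  # seconds
    task_windows: dict = field(
        default_factory=lambda: {
            "baseline": (-500.0, 0.0),
            "encoding": (0.0, 250.0),
            "retention": (250.0, 1250.0),
        }
    )
    groups: tuple[GroupSpec, ...] = (GroupSpec("FT", 20), GroupSpec("VPT", 15))
    conditions: tuple[str, ...] = ("correct", "incorrect")
    n_trials_per_condition: int = 40
    bands: tuple[Band, ...] = DEFAULT_BANDS
    amplitudes: dict = field(default_factory=dict)  # band name -> amplitude, default 1
    planted_networks: tuple[PlantedNetwork, ...] = ()
    noise_sd: float = 1.0
    subject_kappa_sd: float = 0.0  # between-subject jitter of realized kappa
    behaviour_link: BehaviourLink = BehaviourLink()
    p_motion: float = 0.0
    p_spike: float = 0.0
    motion_block_fraction: float = 0.2
    master_seed: int = 0

    # -- helpers ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round((t1 - t0) * self.sampling_rate)) + 1

    @property
    def time(self) -> np.ndarray:
        t0, _ = self.epoch_window
        return t0 + np.arange(self.n_samples) / self.sampling_rate

    def band(self, name: str) -> Band:
        for b in self.bands:
            if b.name == name:
                return b
        raise KeyError(f"unknown band {name!r}")

    def window_ms(self, window: str | tuple[float, float]) -> tuple[float, float]:
        if isinstance(window, str):
            try:
                return tuple(self.task_windows[window])  # type: ignore[return-value]
            except KeyError:
                raise KeyError(f"unknown task window {window!r}") from None
        return tuple(window)  # type: ignore[return-value]

    def amplitude(self, band_name: str) -> float:
        return float(self.amplitudes.get(band_name, 1.0))

    def validate(self) -> None:
        t0_ms, t1_ms = 1000.0 * self.epoch_window[0], 1000.0 * self.epoch_window[1]
        if not t1_ms > t0_ms:
            raise ValueError("epoch_window must be increasing")
        for name, (w0, w1) in self.task_windows.items():
            if not (t0_ms - 1e-9 <= w0 < w1 <= t1_ms + 1e-9):
                raise ValueError(f"task window {name!r} = ({w0}, {w1}) ms lies outside the epoch")
        for g in self.groups:
            if g.n_subjects < 2:
                raise ValueError(f"group {g.label!r} needs >= 2 subjects")
        nyq = self.sampling_rate / 2.0
        for b in self.bands:
            if b.f_high >= nyq:
                raise ValueError(f"band {b.name!r} exceeds the Nyquist frequency {nyq} Hz")
        for net in self.planted_networks:
            self.band(net.band)  # raises on unknown band
            if not 0.0 <= net.kappa <= 1.0:
                raise ValueError(f"kappa must lie in [0, 1], got {net.kappa}")
            if not net.edges:
                raise ValueError("planted network has no edges")
            for (i, j) in net.edges:
                if not (0 <= i < j < self.n_regions):
                    raise ValueError(
                        f"planted edge ({i}, {j}) must satisfy 0 <= i < j < n_regions"
                    )
            w0, w1 = self.window_ms(net.window)
            if not (t0_ms - 1e-9 <= w0 < w1 <= t1_ms + 1e-9):
                raise ValueError("planted-network window lies outside the epoch")
            if net.group is not None and net.group not in [g.label for g in self.groups]:
                raise ValueError(f"planted network references unknown group {net.group!r}")
            if net.condition is not None and net.condition not in self.conditions:
                raise ValueError(
                    f"planted network references unknown condition {net.condition!r}"
                )
        self._check_conflicts()

    def _check_conflicts(self) -> None:
        """Reject contradictory planted specifications.

        Two networks conflict when they could be simultaneously active on the
        same band for some (group, condition, time sample) while sharing a
        node: a node cannot blend towards two different common phases.
        """
        nets = self.planted_networks
        for a_idx in range(len(nets)):
            for b_idx in range(a_idx + 1, len(nets)):
                a, b = nets[a_idx], nets[b_idx]
                if a.band != b.band:
                    continue
                if a.group is not None and b.group is not None and a.group != b.group:
                    continue
                if (
                    a.condition is not None
                    and b.condition is not None
                    and a.condition != b.condition
                ):
                    continue
                aw, bw = self.window_ms(a.window), self.window_ms(b.window)
                if aw[1] <= bw[0] or bw[1] <= aw[0]:
                    continue
                shared = set(a.nodes) & set(b.nodes)
                if shared:
                    raise ValueError(
                        f"conflicting planted networks {a_idx} and {b_idx}: both are "
                        f"active on band {a.band!r} in overlapping windows and share "
                        f"node(s) {sorted(shared)}"
                    )


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort; JSON-serializable.

    Holds the master seed, a config snapshot, the per-subject realized
    coupling strengths and node lags, the seed scheme, and artifact
    contamination labels — enough to regenerate any subject bit-exactly and
    to score every downstream inference.
    """

    master_seed: int
    config: dict
    networks: list
    subjects: list
    seed_scheme: str = (
        "SeedSequence entropy = (master_seed, tag, subject_index[, trial_index]); "
        f"tags: subject={_TAG_SUBJECT}, trial={_TAG_TRIAL}, "
        f"artifact={_TAG_ARTIFACT}, behaviour={_TAG_BEHAVIOUR}"
    )

    def subject(self, subject_id: str) -> dict:
        for rec in self.subjects:
            if rec["subject_id"] == subject_id:
                return rec
        raise KeyError(subject_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=_jsonify)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


class Cohort(NamedTuple):
    epochs: list  # list[SourceEpochs]
    artifacts: dict  # subject_id -> ArtifactTraces
    behaviour: pd.DataFrame
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# phase machinery
# ---------------------------------------------------------------------------

def _phase_processes(
    rng: np.random.Generator, n_series: int, n_samples: int, fs: float, band: Band
) -> np.ndarray:
    """Unwrapped phases (n_series, n_samples) of bounded-drift band oscillators."""
    rho = np.exp(-1.0 / (fs * TAU_FREQ_DRIFT_S))
    sd = FREQ_DRIFT_FRACTION * band.half_width
    eps = rng.standard_normal((n_series, n_samples))
    x0 = sd * rng.standard_normal((n_series, 1))
    innov = sd * np.sqrt(1.0 - rho**2) * eps
    drift, _ = lfilter([1.0], [1.0, -rho], innov, axis=-1, zi=rho * x0)
    clip = FREQ_DRIFT_CLIP * band.half_width
    np.clip(drift, -clip, clip, out=drift)
    phi0 = rng.uniform(0.0, 2.0 * np.pi, (n_series, 1))
    return phi0 + 2.0 * np.pi * np.cumsum(band.center + drift, axis=-1) / fs


def _assign_node_lags(
    rng: np.random.Generator, edges: Sequence[tuple[int, int]], max_iter: int = 2000
) -> dict[int, float]:
    """Per-node lags with every edge's |lag difference| in [LAG_MIN, LAG_MAX] rad."""
    nodes = sorted({v for e in edges for v in e})
    lags = {v: rng.uniform(-_NODE_LAG_RANGE, _NODE_LAG_RANGE) for v in nodes}
    for _ in range(max_iter):
        bad = [e for e in edges if abs(lags[e[0]] - lags[e[1]]) < LAG_MIN_RAD]
        if not bad:
            return lags
        i, j = bad[int(rng.integers(len(bad)))]
        v = i if rng.integers(2) else j
        lags[v] = rng.uniform(-_NODE_LAG_RANGE, _NODE_LAG_RANGE)
    raise RuntimeError(
        "could not assign planted-edge lags satisfying the detectability "
        f"constraint |dlag| >= {LAG_MIN_RAD} rad; the planted graph is too dense"
    )


def _window_gate(time_s: np.ndarray, window_ms: tuple[float, float], fs: float) -> np.ndarray:
    """0..1 gate: 1 inside the window, cosine ramps of RAMP_MS at both edges."""
    mask = window_mask(time_s, window_ms)
    gate = mask.astype(float)
    idx = np.flatnonzero(mask)
    n_ramp = min(int(round(RAMP_MS / 1000.0 * fs)), max(idx.size // 2, 1))
    if n_ramp > 1:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        gate[idx[:n_ramp]] = ramp
        gate[idx[-n_ramp:]] = ramp[::-1]
    return gate


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _subject_rng(master_seed: int, tag: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((master_seed, tag, *counters)))


def _make_trial(
    trial_rng: np.random.Generator,
    config: SimulationConfig,
    active: list[tuple[int, PlantedNetwork, float, dict[int, float]]],
    gates: dict,
    time_s: np.ndarray,
) -> np.ndarray:
    """One trial, (n_regions, n_samples). ``active`` lists the networks live
    on this trial as (index, network, realized kappa, node lags)."""
    n = time_s.size
    x = np.zeros((config.n_regions, n))
    for band in config.bands:
        phi = _phase_processes(trial_rng, config.n_regions, n, config.sampling_rate, band)
        for net_idx, net, kappa_s, lags in active:
            if net.band != band.name:
                continue
            # trial-level mixture: coupled with probability kappa; one
            # common phase per connected component of the planted edge set
            coupled = trial_rng.random() < kappa_s
            for comp in net.components:
                common = _phase_processes(trial_rng, 1, n, config.sampling_rate, band)[0]
                if not coupled:
                    continue
                w = gates[net_idx]
                for node in comp:
                    phi[node] = w * (common + lags[node]) + (1.0 - w) * phi[node]
        x += config.amplitude(band.name) * np.cos(phi)
    x += config.noise_sd * trial_rng.standard_normal(x.shape)
    return x


def make_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort described by ``config``.

    Returns epochs per subject, artifact traces per subject, the behaviour
    table, and the ground-truth record. Deterministic given
    ``config.master_seed``: every random draw flows through a splittable
    per-(subject, trial) seed scheme recorded in the truth object.
    """
    config.validate()
    time_s = config.time
    net_records = [
        {
            "index": k,
            "band": net.band,
            "edges": [list(e) for e in net.edges],
            "kappa_nominal": net.kappa,
            "closure_edges": [list(e) for e in net.synchrony_closure],
            "window_ms": list(config.window_ms(net.window)),
            "group": net.group,
            "condition": net.condition,
        }
        for k, net in enumerate(config.planted_networks)
    ]
    gates = {
        k: _window_gate(time_s, config.window_ms(net.window), config.sampling_rate)
        for k, net in enumerate(config.planted_networks)
    }
    labels = np.repeat(list(config.conditions), config.n_trials_per_condition)

    epochs_list: list[SourceEpochs] = []
    artifacts: dict[str, ArtifactTraces] = {}
    subject_records: list[dict] = []
    s_global = 0
    for grp in config.groups:
        for s_in_grp in range(grp.n_subjects):
            subject_id = f"{grp.label}{s_in_grp:02d}"
            srng = _subject_rng(config.master_seed, _TAG_SUBJECT, s_global)
            # realized coupling and lags for networks targeting this group
            realized: dict[int, float] = {}
            lag_map: dict[int, dict[int, float]] = {}
            for k, net in enumerate(config.planted_networks):
                if net.group is not None and net.group != grp.label:
                    continue
                kappa_s = float(
                    np.clip(net.kappa + config.subject_kappa_sd * srng.standard_normal(), 0.0, 1.0)
                )
                realized[k] = kappa_s
                lag_map[k] = _assign_node_lags(srng, net.edges)
            data = np.empty((labels.size, config.n_regions, config.n_samples))
            for t_idx, label in enumerate(labels):
                active = [
                    (k, config.planted_networks[k], realized[k], lag_map[k])
                    for k in realized
                    if config.planted_networks[k].condition in (None, label)
                ]
                trng = _subject_rng(config.master_seed, _TAG_TRIAL, s_global, t_idx)
                data[t_idx] = _make_trial(trng, config, active, gates, time_s)
            epochs = SourceEpochs(
                data=data,
                time=time_s,
                sampling_rate=config.sampling_rate,
                trial_labels=labels.copy(),
                subject_id=subject_id,
                group=grp.label,
            )
            traces = make_artifact_traces(
                epochs,
                p_motion=config.p_motion,
                p_spike=config.p_spike,
                seed=np.random.SeedSequence((config.master_seed, _TAG_ARTIFACT, s_global)),
                block_fraction=config.motion_block_fraction,
            )
            epochs_list.append(epochs)
            artifacts[subject_id] = traces
            subject_records.append(
                {
                    "subject_id": subject_id,
                    "subject_index": s_global,
                    "group": grp.label,
                    "kappa_realized": {str(k): v for k, v in realized.items()},
                    "kappa_mean": float(np.mean(list(realized.values()))) if realized else 0.0,
                    "node_lags": {
                        str(k): {str(n): float(l) for n, l in lm.items()}
                        for k, lm in lag_map.items()
                    },
                    "motion_contaminated": traces.motion_contaminated.astype(int).tolist(),
                    "spike_contaminated": traces.spike_contaminated.astype(int).tolist(),
                }
            )
            s_global += 1

    truth = SimulationTruth(
        master_seed=config.master_seed,
        config=_config_snapshot(config),
        networks=net_records,
        subjects=subject_records,
    )
    behaviour = make_behaviour_table(truth, config.behaviour_link)
    return Cohort(epochs_list, artifacts, behaviour, truth)


def _config_snapshot(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["groups"] = [[g.label, g.n_subjects] for g in config.groups]
    d["bands"] = [[b.name, b.f_low, b.f_high] for b in config.bands]
    d["planted_networks"] = [
        {
            "band": n.band,
            "edges": [list(e) for e in n.edges],
            "kappa": n.kappa,
            "window": list(config.window_ms(n.window)),
            "group": n.group,
            "condition": n.condition,
        }
        for n in config.planted_networks
    ]
    return d


# ---------------------------------------------------------------------------
# behaviour and artifacts
# ---------------------------------------------------------------------------

_EDU_LEVELS = ("post_secondary", "university", "post_graduate")


def make_behaviour_table(
    truth: SimulationTruth, link: BehaviourLink | None = None
) -> pd.DataFrame:
    """Behaviour/demographics table driven by the realized coupling strengths.

    Accuracy follows ``intercept + slope * kappa_mean + Normal(0, noise_sd)``
    clamped to [0, 100]; demographics (age, sex, maternal education, IQ-like
    score) are drawn per subject from fixed plausible distributions.
    Deterministic given the truth record's master seed.
    """
    if link is None:
        link = BehaviourLink(**truth.config["behaviour_link"])
    elif isinstance(link, dict):
        link = BehaviourLink(**link)
    rows = []
    for rec in truth.subjects:
        rng = _subject_rng(truth.master_seed, _TAG_BEHAVIOUR, rec["subject_index"])
        noise = rng.standard_normal()
        accuracy = float(
            np.clip(link.intercept + link.slope * rec["kappa_mean"] + link.noise_sd * noise,
                    0.0, 100.0)
        )
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "group": rec["group"],
                "age_years": float(np.clip(rng.normal(6.6, 0.35), 5.5, 7.6)),
                "sex": "M" if rng.integers(2) else "F",
                "maternal_education": _EDU_LEVELS[
                    int(rng.choice(3, p=[0.15, 0.60, 0.25]))
                ],
                "iq": float(rng.normal(110.0, 13.0)),
                "accuracy": accuracy,
            }
        )
    return pd.DataFrame(rows)


def make_artifact_traces(
    epochs: SourceEpochs,
    p_motion: float = 0.0,
    p_spike: float = 0.0,
    seed=0,
    block_fraction: float = 0.2,
) -> ArtifactTraces:
    """Synthetic head-position and sensor-peak traces for trial screening.

    With probability ``p_motion`` a trial's head-position trace exceeds 5 mm
    on a contiguous block covering ``block_fraction`` of its samples; with
    probability ``p_spike`` one channel's peak exceeds 2000 fT. Ground-truth
    contamination flags are stored on the returned object. Channels are the
    region traces themselves — an emulation, since no sensor array exists
    for source-space synthetic data.
    """
    if not (0.0 <= p_motion <= 1.0 and 0.0 <= p_spike <= 1.0):
        raise ValueError("contamination probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_trials, n_channels, n_samples = epochs.data.shape
    # clean background: slow wander around ~1.5 mm, strictly below 5 mm
    base = 1.5 + 1.0 * np.sin(
        2.0 * np.pi * rng.uniform(0.1, 0.4, (n_trials, 1)) * epochs.time
        + rng.uniform(0.0, 2.0 * np.pi, (n_trials, 1))
    )
    head = np.clip(base + 0.3 * rng.standard_normal((n_trials, n_samples)), 0.0, 4.5)
    peaks = rng.uniform(300.0, 1800.0, (n_trials, n_channels))

    motion = rng.random(n_trials) < p_motion
    spike = rng.random(n_trials) < p_spike
    block = max(int(round(block_fraction * n_samples)), 1)
    for t in np.flatnonzero(motion):
        start = int(rng.integers(0, n_samples - block + 1))
        head[t, start : start + block] = rng.uniform(5.5, 8.0)
    for t in np.flatnonzero(spike):
        ch = int(rng.integers(n_channels))
        peaks[t, ch] = rng.uniform(2100.0, 3500.0)
    return ArtifactTraces(
        head_position=head,
        peak_amplitude=peaks,
        motion_contaminated=motion,
        spike_contaminated=spike,
    )


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def desk_scale_config(**overrides) -> SimulationConfig:
    """Reduced cohort for interactive work and CI: 30 regions, 40 trials per
    condition, 8 + 8 subjects. The full-scale study profile is simply
    ``SimulationConfig()``."""
    base = dict(
        n_regions=30,
        n_trials_per_condition=40,
        groups=(GroupSpec("FT", 8), GroupSpec("VPT", 8)),
    )
    base.update(overrides)
    return SimulationConfig(**base)
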