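"""File formats and run manifests.

Array containers travel as HDF5 (one file per subject), tables as TSV,
graphs as GraphML, results and manifests as JSON. HDF5 schemas:

* epochs:       datasets ``/data`` (trials x regions x samples), ``/time``,
                ``/labels``; attrs ``sampling_rate``, ``subject_id``,
                ``group``, ``region_labels`` [, ``band``].
* connectivity: datasets ``/wpli`` (samples x N x N), ``/time``; attrs
                ``band``, ``condition``, ``normalized``, ``subject_id``,
                ``group``, ``region_labels`` [, ``baseline_window``].

Datasets are written with ``track_times=False`` so identical inputs yield
bit-identical files, which the manifest digests rely on.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import Band, ConnectivityTimeseries, ScreenReport, SourceEpochs
from .simulate import (
    BehaviourLink,
    GroupSpec,
    PlantedNetwork,
    SimulationConfig,
)

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_connectivity",
    "load_connectivity",
    "save_table",
    "load_table",
    "save_components_tsv",
    "save_components_graphml",
    "write_json",
    "load_config",
    "sha256_of",
    "Manifest",
]

_H5 = dict(track_times=False)


def _require_attr(obj, name: str, path) -> object:
    if name not in obj.attrs:
        raise ValueError(f"{path}: missing required HDF5 attribute {name!r}")
    return obj.attrs[name]


def save_epochs(path, epochs: SourceEpochs) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data, **_H5)
        fh.create_dataset("time", data=epochs.time, **_H5)
        fh.create_dataset(
            "labels", data=np.asarray(epochs.trial_labels, dtype="S"), **_H5
        )
        fh.attrs["sampling_rate"] = epochs.sampling_rate
        fh.attrs["subject_id"] = epochs.subject_id
        fh.attrs["group"] = epochs.group
        fh.attrs["region_labels"] = list(epochs.region_labels)
        if epochs.band is not None:
            fh.attrs["band"] = [epochs.band.name, epochs.band.f_low, epochs.band.f_high]


def load_epochs(path) -> SourceEpochs:
    with h5py.File(path, "r") as fh:
        for ds in ("data", "time", "labels"):
            if ds not in fh:
                raise ValueError(f"{path}: missing required dataset /{ds}")
        band = None
        if "band" in fh.attrs:
            name, lo, hi = fh.attrs["band"]
            band = Band(str(name), float(lo), float(hi))
        return SourceEpochs(
            data=fh["data"][()],
            time=fh["time"][()],
            sampling_rate=float(_require_attr(fh, "sampling_rate", path)),
            trial_labels=fh["labels"][()].astype(str),
            subject_id=str(_require_attr(fh, "subject_id", path)),
            group=str(_require_attr(fh, "group", path)),
            region_labels=tuple(str(r) for r in _require_attr(fh, "region_labels", path)),
            band=band,
        )


def save_connectivity(path, conn: ConnectivityTimeseries) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("wpli", data=conn.values, **_H5)
        fh.create_dataset("time", data=conn.time, **_H5)
        fh.attrs["band"] = conn.band
        fh.attrs["condition"] = conn.condition
        fh.attrs["normalized"] = int(conn.normalized)
        fh.attrs["subject_id"] = conn.subject_id
        fh.attrs["group"] = conn.group
        fh.attrs["region_labels"] = list(conn.region_labels)
        if conn.baseline_window is not None:
            fh.attrs["baseline_window"] = list(conn.baseline_window)


def load_connectivity(path) -> ConnectivityTimeseries:
    with h5py.File(path, "r") as fh:
        for ds in ("wpli", "time"):
            if ds not in fh:
                raise ValueError(f"{path}: missing required dataset /{ds}")
        baseline = None
        if "baseline_window" in fh.attrs:
            baseline = tuple(float(v) for v in fh.attrs["baseline_window"])
        return ConnectivityTimeseries(
            values=fh["wpli"][()],
            time=fh["time"][()],
            band=str(_require_attr(fh, "band", path)),
            condition=str(_require_attr(fh, "condition", path)),
            normalized=bool(int(_require_attr(fh, "normalized", path))),
            subject_id=str(_require_attr(fh, "subject_id", path)),
            group=str(_require_attr(fh, "group", path)),
            region_labels=tuple(str(r) for r in _require_attr(fh, "region_labels", path)),
            baseline_window=baseline,
        )


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_screen_report(path, report: ScreenReport) -> None:
    save_table(path, report.to_dataframe())


def save_components_tsv(path, components, region_labels=None) -> None:
    """Edge list TSV: component, region_i, region_j, label_i, label_j."""
    rows = []
    for c_idx, comp in enumerate(components):
        for i, j in comp.edges:
            rows.append(
                {
                    "component": c_idx,
                    "region_i": i,
                    "region_j": j,
                    "label_i": region_labels[i] if region_labels else str(i),
                    "label_j": region_labels[j] if region_labels else str(j),
                    "p_corrected": comp.p_corrected,
                }
            )
    save_table(path, pd.DataFrame(rows))


def save_components_graphml(path, components, region_labels=None) -> None:
    g = nx.Graph()
    for c_idx, comp in enumerate(components):
        for node in comp.nodes:
            g.add_node(
                node,
                label=region_labels[node] if region_labels else str(node),
                degree=comp.node_degree[node],
                component=c_idx,
            )
        for i, j in comp.edges:
            g.add_edge(i, j, component=c_idx)
    nx.write_graphml(g, path)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, cls=_NumpyEncoder)
        fh.write("\n")


def load_config(path) -> SimulationConfig:
    """Read a simulation config from a YAML/JSON document.

    The document mirrors ``SimulationConfig`` field for field; lists stand
    in for tuples, e.g. ``groups: [[FT, 8], [VPT, 8]]`` and
    ``bands: [[alpha, 8, 14]]``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> SimulationConfig:
    doc = dict(doc)
    if "groups" in doc:
        doc["groups"] = tuple(GroupSpec(str(g[0]), int(g[1])) for g in doc["groups"])
    if "bands" in doc:
        doc["bands"] = tuple(Band(str(b[0]), float(b[1]), float(b[2])) for b in doc["bands"])
    if "behaviour_link" in doc and isinstance(doc["behaviour_link"], dict):
        doc["behaviour_link"] = BehaviourLink(**doc["behaviour_link"])
    if "planted_networks" in doc:
        nets = []
        for n in doc["planted_networks"]:
            n = dict(n)
            n["edges"] = tuple(tuple(int(v) for v in e) for e in n["edges"])
            if isinstance(n.get("window"), list):
                n["window"] = tuple(n["window"])
            nets.append(PlantedNetwork(**n))
        doc["planted_networks"] = tuple(nets)
    for key in ("epoch_window", "conditions"):
        if key in doc:
            doc[key] = tuple(doc[key])
    if "task_windows" in doc:
        doc["task_windows"] = {k: tuple(v) for k, v in doc["task_windows"].items()}
    return SimulationConfig(**doc)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Stage-by-stage record of a pipeline run: inputs, outputs, digests,
    parameters and seeds — sufficient to verify an identical re-run."""

    def __init__(self, path):
        self.path = Path(path)
        if self.path.exists():
            with open(self.path) as fh:
                self.doc = json.load(fh)
        else:
            self.doc = {"package_version": __version__, "stages": []}

    def add_stage(self, name: str, inputs=(), outputs=(), params=None) -> None:
        self.doc["stages"].append(
            {
                "stage": name,
                "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                "inputs": {str(p): sha256_of(p) for p in inputs},
                "outputs": {str(p): sha256_of(p) for p in outputs},
                "params": params or {},
            }
        )
        write_json(self.path, self.doc)

    def output_digests(self) -> dict:
        out = {}
        for stage in self.doc["stages"]:
            out.update(stage["outputs"])
        return out

    def verify_outputs(self) -> bool:
        """Re-digest every recorded output; True iff all match."""
        return all(
            sha256_of(p) == d for p, d in self.output_digests().items()
        )
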