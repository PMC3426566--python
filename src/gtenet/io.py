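"""Readers and writers for the package's text and HDF5 formats.

Conventions: tab-delimited text with '.' decimal separator; times in
seconds, positions in mm; every writer emits a commented header naming the
columns and units, and every emitted file is parseable by the matching
reader (round-trip tested).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import SpikeRecord
from .errors import StructuralError
from .fluorescence import FluorescenceRecording
from .inference import EstimatorSpec, ScoreMatrix
from .topology import DirectedNetwork

__all__ = [
    "write_adjacency",
    "read_adjacency",
    "write_edge_list",
    "read_edge_list",
    "write_positions",
    "read_positions",
    "write_spikes",
    "read_spikes",
    "write_fluorescence_text",
    "read_fluorescence_text",
    "write_fluorescence_h5",
    "read_fluorescence_h5",
    "write_scores",
    "read_scores",
]


def write_adjacency(path, net: DirectedNetwork) -> None:
    """Dense 0/1 adjacency, row = source, column = target."""
    header = "# adjacency matrix, row=source col=target, 0/1"
    np.savetxt(path, net.adjacency.astype(np.int8), fmt="%d", delimiter="\t", header=header.lstrip("# "))


def read_adjacency(path, positions: np.ndarray | None = None) -> DirectedNetwork:
    a = np.loadtxt(path, dtype=np.int8, delimiter="\t")
    return DirectedNetwork(a.astype(bool), positions, {"source": str(path)})


def write_edge_list(path, net: DirectedNetwork) -> None:
    """Two-column (source, target) 0-based edge list."""
    src, dst = np.nonzero(net.adjacency)
    np.savetxt(
        path,
        np.column_stack([src, dst]),
        fmt="%d",
        delimiter="\t",
        header="source\ttarget (0-based node ids)",
    )


def read_edge_list(path, n_nodes: int | None = None, positions=None) -> DirectedNetwork:
    data = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
    if data.size == 0:
        if n_nodes is None:
            raise StructuralError("empty edge list needs an explicit n_nodes")
        a = np.zeros((n_nodes, n_nodes), dtype=bool)
        return DirectedNetwork(a, positions, {"source": str(path)})
    n = n_nodes if n_nodes is not None else int(data.max()) + 1
    a = np.zeros((n, n), dtype=bool)
    a[data[:, 0], data[:, 1]] = True
    return DirectedNetwork(a, positions, {"source": str(path)})


def write_positions(path, net_or_pos) -> None:
    """Three columns: node id, x (mm), y (mm)."""
    pos = net_or_pos.positions if isinstance(net_or_pos, DirectedNetwork) else np.asarray(net_or_pos)
    ids = np.arange(pos.shape[0])
    np.savetxt(
        path,
        np.column_stack([ids, pos]),
        fmt=("%d", "%.8g", "%.8g"),
        delimiter="\t",
        header="id\tx_mm\ty_mm",
    )


def read_positions(path) -> np.ndarray:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    order = np.argsort(data[:, 0])
    return data[order, 1:3]


def write_spikes(path, spikes: SpikeRecord) -> None:
    """Two-column raster (time_s, neuron_id) sorted by time, plus a JSON
    sidecar ``<path>.meta.json`` holding duration, neuron count, seed and
    the parameter snapshot."""
    order = np.argsort(spikes.times, kind="stable")
    np.savetxt(
        path,
        np.column_stack([spikes.times[order], spikes.neurons[order]]),
        fmt=("%.6f", "%d"),
        delimiter="\t",
        header="time_s\tneuron_id",
    )
    meta = {
        "duration": spikes.duration,
        "n_neurons": spikes.n_neurons,
        "seed": spikes.seed,
        "params": spikes.params,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, default=float))


def read_spikes(path) -> SpikeRecord:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise StructuralError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    times = data[:, 0] if data.size else np.empty(0)
    neurons = data[:, 1].astype(np.int64) if data.size else np.empty(0, np.int64)
    return SpikeRecord(
        times=times,
        neurons=neurons,
        n_neurons=int(meta["n_neurons"]),
        duration=float(meta["duration"]),
        params=meta.get("params", {}),
        seed=meta.get("seed"),
    )


def write_fluorescence_text(path, rec: FluorescenceRecording) -> None:
    """First column time_s, then one column per neuron."""
    t = np.arange(rec.n_frames) * rec.frame_interval
    cols = "\t".join(f"n{i}" for i in range(rec.n_neurons))
    np.savetxt(
        path,
        np.column_stack([t, rec.data]),
        fmt="%.8g",
        delimiter="\t",
        header="time_s\t" + cols,
    )


def read_fluorescence_text(path, positions: np.ndarray | None = None) -> FluorescenceRecording:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if data.shape[0] < 2:
        raise StructuralError("fluorescence file needs at least two frames")
    t = data[:, 0]
    dt = float(np.median(np.diff(t)))
    return FluorescenceRecording(data[:, 1:], dt, positions=positions,
                                 provenance={"source": str(path)})


def write_fluorescence_h5(path, rec: FluorescenceRecording) -> None:
    """HDF5 container with datasets ``F`` (frames x N, float64), scalar
    ``dt`` (s) and optional ``positions`` (N x 2, mm)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("F", data=rec.data.astype(np.float64))
        f.create_dataset("dt", data=float(rec.frame_interval))
        if rec.positions is not None:
            f.create_dataset("positions", data=rec.positions.astype(np.float64))
        f.attrs["provenance"] = json.dumps(rec.provenance, default=float)


def read_fluorescence_h5(path) -> FluorescenceRecording:
    with h5py.File(path, "r") as f:
        data = f["F"][()]
        dt = float(f["dt"][()])
        pos = f["positions"][()] if "positions" in f else None
        prov = json.loads(f.attrs.get("provenance", "{}"))
    return FluorescenceRecording(data, dt, positions=pos, provenance=prov)


def write_scores(path, scores: ScoreMatrix) -> None:
    """Dense score matrix plus a JSON sidecar with the estimator spec."""
    np.savetxt(path, scores.values, fmt="%.10g", delimiter="\t",
               header="score matrix, row=source col=target, diagonal nan")
    sidecar = {
        # JSON has no +-inf: unbounded conditioning levels round-trip as null
        "spec": {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                 for k, v in scores.spec.__dict__.items()},
        "n_samples": scores.n_samples,
        "warnings": scores.warnings,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_scores(path) -> ScoreMatrix:
    vals = np.loadtxt(path, delimiter="\t", ndmin=2)
    meta_path = Path(str(path) + ".meta.json")
    spec = EstimatorSpec()
    n_samples = 0
    warns: list = []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        raw = dict(meta.get("spec", {}))
        for key in ("cond_low", "cond_high"):
            if raw.get(key) is None:
                raw[key] = float("-inf") if key == "cond_low" else float("inf")
        spec = EstimatorSpec(**raw)
        n_samples = int(meta.get("n_samples", 0))
        warns = meta.get("warnings", [])
    return ScoreMatrix(values=vals, spec=spec, n_samples=n_samples, warnings=warns)
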