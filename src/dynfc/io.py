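"""Readers and writers for epochs, graph sequences and pipeline reports.

Epoch containers
----------------
* HDF5: dataset ``/epochs`` (trials x channels x samples) with attributes
  ``fs`` (Hz) and ``t0`` (ms); the PLV tensor is stored under ``/plv`` with
  a pair-index table, graph sequences under ``/graphs``.
* Delimited text: one whitespace/comma-delimited matrix (samples x
  channels) per trial, all trials sharing fs and t0.

Graph sequences can also round-trip through a directory of per-time-point
adjacency CSVs with a JSON manifest, and export as an edge-list TSV
(time_ms, node_i, node_j, weight).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .events import EventIntervals
from .graphs import GraphSequence
from .inference import SignificanceMask
from .keygraph import KeyGraph, upper_triangle_index
from .synchrony import PLVTensor

__all__ = [
    "save_epochs_h5",
    "load_epochs_h5",
    "load_epochs_txt",
    "save_plv_h5",
    "load_plv_h5",
    "save_graphs_h5",
    "load_graphs_h5",
    "save_graphs_csv_dir",
    "load_graphs_csv_dir",
    "graphs_edge_list",
    "distance_series_csv",
    "intervals_json",
    "keygraph_csv",
    "significance_tsv",
]


def save_epochs_h5(path, epochs: np.ndarray, fs: float, t0: float = 0.0) -> None:
    epochs = np.asarray(epochs)
    if epochs.ndim != 3:
        raise ValueError("epochs must be trials x channels x samples")
    with h5py.File(path, "w") as f:
        d = f.create_dataset("epochs", data=epochs)
        d.attrs["fs"] = float(fs)
        d.attrs["t0"] = float(t0)


def load_epochs_h5(path) -> tuple[np.ndarray, float, float]:
    """Returns (epochs, fs, t0)."""
    with h5py.File(path, "r") as f:
        d = f["epochs"]
        return d[()], float(d.attrs["fs"]), float(d.attrs["t0"])


def load_epochs_txt(paths, fs: float, t0: float = 0.0, delimiter=None) -> tuple[np.ndarray, float, float]:
    """Load one samples x channels delimited-text matrix per trial."""
    mats = []
    for p in paths:
        m = np.loadtxt(p, delimiter=delimiter)
        if m.ndim == 1:
            m = m[:, None]
        mats.append(m.T)  # -> channels x samples
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"trial files have inconsistent shapes: {shapes}")
    return np.stack(mats), float(fs), float(t0)


def save_plv_h5(path, plv: PLVTensor) -> None:
    with h5py.File(path, "a") as f:
        if "plv" in f:
            del f["plv"]
        g = f.create_group("plv")
        g.create_dataset("values", data=plv.values)
        g.create_dataset("pair_index", data=np.asarray(plv.pair_index, dtype=np.int64))
        g.create_dataset("time_axis", data=np.asarray(plv.time_axis))
        g.create_dataset("freq_axis", data=np.asarray(plv.freq_axis))
        g.attrs["n_trials"] = int(plv.n_trials)
        if plv.n_valid is not None:
            g.create_dataset("n_valid", data=plv.n_valid)


def load_plv_h5(path) -> PLVTensor:
    with h5py.File(path, "r") as f:
        g = f["plv"]
        return PLVTensor(
            values=g["values"][()],
            pair_index=[tuple(p) for p in g["pair_index"][()]],
            n_trials=int(g.attrs["n_trials"]),
            time_axis=g["time_axis"][()],
            freq_axis=g["freq_axis"][()],
            n_valid=g["n_valid"][()] if "n_valid" in g else None,
        )


def save_graphs_h5(path, seq: GraphSequence) -> None:
    with h5py.File(path, "a") as f:
        if "graphs" in f:
            del f["graphs"]
        g = f.create_group("graphs")
        g.create_dataset("adjacency", data=seq.adjacency)
        g.create_dataset("time_axis", data=seq.time_axis)
        if seq.band is not None:
            g.attrs["band"] = list(seq.band)
        if seq.subject_id is not None:
            g.attrs["subject_id"] = seq.subject_id


def load_graphs_h5(path) -> GraphSequence:
    with h5py.File(path, "r") as f:
        g = f["graphs"]
        band = tuple(g.attrs["band"]) if "band" in g.attrs else None
        sid = str(g.attrs["subject_id"]) if "subject_id" in g.attrs else None
        return GraphSequence(
            adjacency=g["adjacency"][()],
            time_axis=g["time_axis"][()],
            band=band,
            subject_id=sid,
        )


def save_graphs_csv_dir(directory, seq: GraphSequence) -> None:
    """One adjacency CSV per time point plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = len(str(seq.n_times - 1))
    files = []
    for t in range(seq.n_times):
        name = f"graph_{t:0{width}d}.csv"
        np.savetxt(directory / name, seq.adjacency[t], delimiter=",")
        files.append(name)
    manifest = {
        "n_nodes": seq.n_nodes,
        "n_times": seq.n_times,
        "time_axis_ms": seq.time_axis.tolist(),
        "band_hz": list(seq.band) if seq.band is not None else None,
        "subject_id": seq.subject_id,
        "files": files,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_graphs_csv_dir(directory) -> GraphSequence:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    A = np.stack(
        [
            np.loadtxt(directory / name, delimiter=",", ndmin=2)
            for name in manifest["files"]
        ]
    )
    band = tuple(manifest["band_hz"]) if manifest.get("band_hz") else None
    return GraphSequence(
        adjacency=A,
        time_axis=np.asarray(manifest["time_axis_ms"], dtype=float),
        band=band,
        subject_id=manifest.get("subject_id"),
    )


def graphs_edge_list(seq: GraphSequence) -> pd.DataFrame:
    """Long-format edge list: time_ms, node_i, node_j, weight (i < j)."""
    r, c = upper_triangle_index(seq.n_nodes)
    frames = []
    for t in range(seq.n_times):
        frames.append(
            pd.DataFrame(
                {
                    "time_ms": seq.time_axis[t],
                    "node_i": r,
                    "node_j": c,
                    "weight": seq.adjacency[t][r, c],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def distance_series_csv(path, mean_dist: np.ndarray, transition_time_ms: np.ndarray) -> None:
    pd.DataFrame(
        {"transition_time_ms": transition_time_ms, "D": mean_dist}
    ).to_csv(path, index=False)


def intervals_json(path, ev: EventIntervals) -> None:
    payload = [
        {"start_ms": iv.start_ms, "end_ms": iv.end_ms, "n_graphs": iv.n_graphs}
        for iv in ev.intervals
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def keygraph_csv(path_csv, key: KeyGraph, path_tsv=None) -> None:
    """Adjacency CSV plus optional edge-list TSV (node_i, node_j, weight)."""
    np.savetxt(path_csv, key.adjacency, delimiter=",")
    if path_tsv is not None:
        r, c = upper_triangle_index(key.n_nodes)
        pd.DataFrame(
            {"node_i": r, "node_j": c, "weight": key.adjacency[r, c]}
        ).to_csv(path_tsv, sep="\t", index=False)


def significance_tsv(path, key: KeyGraph, mask: SignificanceMask) -> None:
    r, c = upper_triangle_index(key.n_nodes)
    pd.DataFrame(
        {
            "node_i": r,
            "node_j": c,
            "weight": key.adjacency[r, c],
            "p_value": mask.p_values,
            "sig_01": mask.mask_01.astype(int),
            "sig_001": mask.mask_001.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)
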