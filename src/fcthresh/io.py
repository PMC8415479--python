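"""File formats: matrices (Matrix Market / CSV), spike trains (CSV), and
structural-network bundles (matrix + sidecar + JSON metadata).

Conventions: matrix entry (i, j) is the connection i -> j; neuron ids are
0-based; times are milliseconds stored as floating point.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .simulator import SpikeTrainSet
from .topologies import StructuralNetwork

__all__ = [
    "read_matrix", "write_matrix",
    "read_spikes", "write_spikes",
    "save_network", "load_network",
]


def _infer_format(path, fmt):
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".mtx", ".mm"):
        return "matrix-market"
    return "csv"


def write_matrix(matrix, path, fmt: str | None = None) -> None:
    """Write a square matrix as Matrix Market (sparse coordinate) or CSV."""
    matrix = np.asarray(matrix, dtype=float)
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        mmwrite(str(path), coo_matrix(matrix))
    elif fmt == "csv":
        np.savetxt(path, matrix, delimiter=",", fmt="%.17g")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path, fmt: str | None = None) -> np.ndarray:
    """Read a square matrix; explicit zeros in coordinate files are dropped
    from the support (with a log note via warning)."""
    fmt = _infer_format(path, fmt)
    if fmt == "matrix-market":
        m = mmread(str(path))
        if hasattr(m, "toarray"):
            if hasattr(m, "data") and np.any(m.data == 0):
                warnings.warn("explicit zeros in coordinate file dropped from support")
            m = m.toarray()
        matrix = np.asarray(m, dtype=float)
    elif fmt == "csv":
        try:
            matrix = np.loadtxt(path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"{path}: expected a square matrix, got {matrix.shape}")
    return matrix


def write_spikes(spikes: SpikeTrainSet, path) -> None:
    """Two-column CSV (neuron_id, time_ms) with a commented header carrying
    the neuron count and duration."""
    with open(path, "w") as fh:
        fh.write(f"# n_neurons={spikes.n_neurons} duration_ms={spikes.duration_ms}\n")
        fh.write("neuron_id,time_ms\n")
        for i, t in zip(spikes.neuron_ids, spikes.times):
            fh.write(f"{int(i)},{t:.17g}\n")


def read_spikes(path, n_neurons: int | None = None,
                duration_ms: float | None = None) -> SpikeTrainSet:
    """Read a spike-train CSV; header values are used unless overridden."""
    header = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                header[k] = float(v)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if not {"neuron_id", "time_ms"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns neuron_id,time_ms")
    ids = df["neuron_id"].to_numpy(dtype=np.int64)
    times = df["time_ms"].to_numpy(dtype=float)
    if np.any(times < 0):
        raise ValueError(f"{path}: negative spike times")
    n = int(n_neurons if n_neurons is not None
            else header.get("n_neurons", ids.max() + 1 if ids.size else 0))
    if ids.size and (ids.min() < 0 or ids.max() >= n):
        raise ValueError(
            f"{path}: neuron id {int(ids.max())} outside [0, {n})"
        )
    dur = float(duration_ms if duration_ms is not None
                else header.get("duration_ms", times.max() if times.size else 0.0))
    if np.any(np.diff(times) < 0):
        warnings.warn(f"{path}: spike times unsorted, sorting on read")
    return SpikeTrainSet(ids, times, n, dur, metadata={"source": str(path)})


def save_network(net: StructuralNetwork, prefix) -> None:
    """Write a structural network as <prefix>.mtx (weights), <prefix>.csv
    (per-neuron type + per-link delays) and <prefix>.json (metadata)."""
    prefix = Path(prefix)
    write_matrix(net.adjacency, prefix.with_suffix(".mtx"), "matrix-market")
    src, tgt = np.nonzero(net.adjacency)
    pd.DataFrame({
        "source": src, "target": tgt,
        "delay_ms": net.delays[src, tgt],
    }).to_csv(prefix.with_suffix(".links.csv"), index=False)
    pd.DataFrame({
        "neuron_id": np.arange(net.n_neurons),
        "neuron_type": net.neuron_types,
    }).to_csv(prefix.with_suffix(".neurons.csv"), index=False)
    meta = {
        "n_neurons": net.n_neurons,
        "n_excitatory": net.n_excitatory,
        "topology_tag": net.topology_tag,
        "rng_seed": net.rng_seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in net.params.items()},
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_network(prefix) -> StructuralNetwork:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    A = read_matrix(prefix.with_suffix(".mtx"), "matrix-market")
    links = pd.read_csv(prefix.with_suffix(".links.csv"))
    neurons = pd.read_csv(prefix.with_suffix(".neurons.csv"))
    D = np.zeros_like(A, dtype=np.int64)
    D[links["source"], links["target"]] = links["delay_ms"]
    net = StructuralNetwork(
        n_neurons=int(meta["n_neurons"]),
        n_excitatory=int(meta["n_excitatory"]),
        adjacency=A,
        delays=D,
        neuron_types=neurons["neuron_type"].to_numpy(),
        topology_tag=meta["topology_tag"],
        rng_seed=int(meta["rng_seed"]),
        params=meta.get("params", {}),
    )
    net.validate()
    return net
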