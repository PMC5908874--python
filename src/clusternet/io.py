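"""Readers and writers: configs, matrices, tables, manifests.

Tables are written as RFC-4180 CSV ('.' decimal separator, header row,
floats at 12 significant digits) with a JSON mirror.  Weight matrices
round-trip through sparse-triplet text ``(row, col, weight)`` or HDF5;
cluster assignments through two-column TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import __version__
from .balance import NetworkSpec
from .connectivity import ClusterSpec, WeightMatrix

__all__ = [
    "load_network_spec",
    "save_network_spec",
    "save_matrix_triplet",
    "load_matrix_triplet",
    "save_matrix_hdf5",
    "load_matrix_hdf5",
    "save_assignment_tsv",
    "write_tables",
    "write_manifest",
]

FLOAT_FMT = "%.12g"


def load_network_spec(path) -> NetworkSpec:
    """Network spec from a flat YAML/JSON mapping (unknown keys rejected)."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} is not a flat mapping")
    return NetworkSpec.from_dict(data)


def save_network_spec(spec: NetworkSpec, path) -> None:
    path = Path(path)
    d = spec.to_dict()
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(d, fh, indent=1)
        else:
            yaml.safe_dump(d, fh)


def save_matrix_triplet(wm: WeightMatrix, path) -> None:
    """Sparse triplet text: header line ``# N n_exc`` then ``row col weight``."""
    coo = sp.coo_matrix(wm.matrix)
    with open(path, "w") as fh:
        fh.write(f"# {wm.N} {wm.n_exc}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r} {c} {FLOAT_FMT % v}\n")


def load_matrix_triplet(path) -> sp.csr_matrix:
    with open(path) as fh:
        header = fh.readline().split()
        N = int(header[1])
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.split()
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    return sp.csr_matrix((vals, (rows, cols)), shape=(N, N))


def save_matrix_hdf5(wm: WeightMatrix, path) -> None:
    csr = sp.csr_matrix(wm.matrix)
    with h5py.File(path, "w") as fh:
        fh.attrs["N"] = wm.N
        fh.attrs["n_exc"] = wm.n_exc
        fh.attrs["seed"] = wm.seed
        fh.create_dataset("data", data=csr.data)
        fh.create_dataset("indices", data=csr.indices)
        fh.create_dataset("indptr", data=csr.indptr)


def load_matrix_hdf5(path) -> sp.csr_matrix:
    with h5py.File(path, "r") as fh:
        N = int(fh.attrs["N"])
        return sp.csr_matrix(
            (fh["data"][:], fh["indices"][:], fh["indptr"][:]), shape=(N, N))


def save_assignment_tsv(cluster: ClusterSpec, path, n_exc: int) -> None:
    """Two-column TSV ``unit_id <TAB> cluster_id`` (E units first, -1 = none)."""
    with open(path, "w") as fh:
        fh.write("unit_id\tcluster_id\n")
        for i, c in enumerate(cluster.assignment_E):
            fh.write(f"{i}\t{c}\n")
        if cluster.assignment_I is not None:
            for i, c in enumerate(cluster.assignment_I):
                fh.write(f"{n_exc + i}\t{c}\n")


def save_spikes(result, path) -> None:
    """Two-column text ``time_ms unit_id`` (0-based unit ids, E units first)."""
    with open(path, "w") as fh:
        fh.write("time_ms\tunit_id\n")
        for t, u in zip(result.spike_times, result.spike_units):
            fh.write(f"{FLOAT_FMT % t}\t{u}\n")


def write_tables(tables: dict, outdir, formats=("csv", "json")) -> list:
    """Write named DataFrames as CSV and/or JSON; returns written paths."""
    if not tables:
        raise ValueError("no tables to write")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
        if "csv" in formats:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format=FLOAT_FMT,
                      lineterminator="\r\n")
            written.append(p)
        if "json" in formats:
            p = outdir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(json.loads(df.to_json(orient="records",
                                                double_precision=12)),
                          fh, indent=1)
            written.append(p)
    return written


def write_manifest(outdir, config: dict, seed: int) -> Path:
    """Record everything needed to re-run an experiment bit-identically."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "clusternet_version": __version__,
        "numpy_version": np.__version__,
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return path
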