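"""Readers and writers for connectome stacks, covariates and parcellations.

Three interchangeable connectome formats are supported:

* long-format delimited text with header ``subject_id,i,j,z`` (absent pairs
  are missing edges);
* one square delimited matrix per subject plus a manifest file mapping
  ``subject_id`` to a path;
* a single HDF5 container with datasets ``/subjects``, ``/values``,
  ``/missing`` and an ``n_nodes`` attribute.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .core import ConnectomeStack, EdgeIndex, ParcellationInfo, SubjectTable, edge_count


def read_long_edges(path, n_nodes: int, sep=",") -> ConnectomeStack:
    """Load a stack from ``subject_id,i,j,z`` rows; unlisted edges are missing."""
    df = pd.read_csv(path, sep=sep)
    required = {"subject_id", "i", "j", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"long-format file needs columns {sorted(required)}")
    idx = EdgeIndex(n_nodes)
    subject_ids = list(dict.fromkeys(df["subject_id"].astype(str)))
    row_of = {s: k for k, s in enumerate(subject_ids)}
    n_edges = edge_count(n_nodes)
    values = np.zeros((len(subject_ids), n_edges))
    missing = np.ones((len(subject_ids), n_edges), dtype=bool)
    i = df["i"].to_numpy(dtype=int)
    j = df["j"].to_numpy(dtype=int)
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    if (lo == hi).any() or (hi >= n_nodes).any() or (lo < 0).any():
        raise ValueError("edge rows must reference distinct nodes in 0..N-1")
    cols = lo * (2 * n_nodes - lo - 1) // 2 + (hi - lo - 1)
    rows = df["subject_id"].astype(str).map(row_of).to_numpy()
    z = df["z"].to_numpy(dtype=float)
    values[rows, cols] = z
    missing[rows, cols] = ~np.isfinite(z)
    return ConnectomeStack(subject_ids, n_nodes, values, missing)


def write_long_edges(stack: ConnectomeStack, path, sep=",") -> None:
    pairs = stack.edge_index.pairs
    frames = []
    for k, sid in enumerate(stack.subject_ids):
        obs = ~stack.missing[k]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "i": pairs[obs, 0],
                    "j": pairs[obs, 1],
                    "z": stack.values[k, obs],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_matrix_manifest(manifest_path, sep=",") -> ConnectomeStack:
    """Load square per-subject matrices listed in a ``subject_id,path`` manifest.

    Relative paths are resolved against the manifest's directory.  NaN entries
    mark missing edges.
    """
    manifest = pd.read_csv(manifest_path, sep=sep)
    if not {"subject_id", "path"}.issubset(manifest.columns):
        raise ValueError("manifest needs columns subject_id,path")
    base = os.path.dirname(os.path.abspath(manifest_path))
    mats, ids = [], []
    for _, row in manifest.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        mats.append(np.loadtxt(p, delimiter=sep))
        ids.append(str(row["subject_id"]))
    return ConnectomeStack.from_matrices(ids, mats)


def read_hdf5(path) -> ConnectomeStack:
    with h5py.File(path, "r") as f:
        subject_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["subjects"][:]]
        values = f["values"][:]
        missing = f["missing"][:].astype(bool) if "missing" in f else None
        n_nodes = int(f.attrs["n_nodes"])
    return ConnectomeStack(subject_ids, n_nodes, values, missing)


def write_hdf5(stack: ConnectomeStack, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "subjects", data=np.array(stack.subject_ids, dtype=h5py.string_dtype())
        )
        f.create_dataset("values", data=stack.values)
        f.create_dataset("missing", data=stack.missing)
        f.attrs["n_nodes"] = stack.n_nodes


def read_parcellation(path, sep=",") -> ParcellationInfo:
    return ParcellationInfo(pd.read_csv(path, sep=sep))


def write_parcellation(parc: ParcellationInfo, path, sep=",") -> None:
    parc.df.to_csv(path, sep=sep, index=False)


def read_covariates(path, sep=",") -> SubjectTable:
    return SubjectTable(pd.read_csv(path, sep=sep))


def write_covariates(table: SubjectTable, path, sep=",") -> None:
    table.df.to_csv(path, sep=sep, index=False)
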