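"""Plain-text persistence for every pipeline artifact.

Formats are deliberately simple and diff-able: delimited numeric
matrices, a YAML manifest for time-series metadata, a sparse
(row, col, weight) triplet file for the supra-adjacency, and TSV tables
for per-node results.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    ConnectivityBlock,
    DCIResult,
    GroupResult,
    HubTable,
    SourceTimeSeriesSet,
    StructuralMatrix,
    SupraAdjacency,
)

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_structural",
    "read_structural",
    "write_blocks",
    "read_blocks",
    "write_supra",
    "read_supra",
    "hub_table_frame",
    "dci_frame",
    "group_frame",
]

_MANIFEST = "manifest.yaml"


def write_timeseries(ts: SourceTimeSeriesSet, directory: str | Path) -> Path:
    """One whitespace-delimited file per trial (rows=nodes) plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r in range(ts.n_trials):
        np.savetxt(directory / f"trial{r:03d}.txt", ts.data[:, :, r])
    manifest = {
        "fs": float(ts.fs),
        "epoch": [float(ts.epoch[0]), float(ts.epoch[1])],
        "labels": list(ts.labels),
        "n_trials": int(ts.n_trials),
    }
    (directory / _MANIFEST).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return directory


def read_timeseries(directory: str | Path) -> SourceTimeSeriesSet:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / _MANIFEST).read_text())
    trials = [
        np.loadtxt(directory / f"trial{r:03d}.txt", ndmin=2)
        for r in range(manifest["n_trials"])
    ]
    data = np.stack(trials, axis=2)
    return SourceTimeSeriesSet(
        data, manifest["fs"], tuple(manifest["epoch"]), manifest["labels"]
    )


def write_structural(sc: StructuralMatrix, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, sc.mat, fmt="%d")
    return path


def read_structural(path: str | Path, labels: list[str] | None = None) -> StructuralMatrix:
    mat = np.loadtxt(path, ndmin=2).astype(int)
    return StructuralMatrix(mat=mat, labels=labels or [])


def write_blocks(
    blocks: list[ConnectivityBlock],
    directory: str | Path,
    bins=None,
    window=None,
    prefix: str = "conn",
) -> Path:
    """Each block as ``{prefix}_b{A}_b{B}.tsv`` plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for b in blocks:
        np.savetxt(directory / f"{prefix}_b{b.binA}_b{b.binB}.tsv", b.mat, delimiter="\t")
    sidecar = {
        "blocks": [[b.binA, b.binB] for b in blocks],
        "n_nodes": blocks[0].n_nodes,
    }
    if bins is not None:
        sidecar["bins"] = [[fb.low_hz, fb.high_hz] for fb in bins]
    if window is not None:
        sidecar["window"] = list(window)
    (directory / f"{prefix}_blocks.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def read_blocks(directory: str | Path, prefix: str = "conn") -> list[ConnectivityBlock]:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{prefix}_blocks.json").read_text())
    return [
        ConnectivityBlock(
            a, b, np.loadtxt(directory / f"{prefix}_b{a}_b{b}.tsv", delimiter="\t", ndmin=2)
        )
        for a, b in sidecar["blocks"]
    ]


def write_supra(supra: SupraAdjacency, path: str | Path) -> Path:
    """Sparse triplet text: header line with N and B, then row col weight."""
    path = Path(path)
    rows, cols = np.nonzero(np.triu(supra.mat))
    with open(path, "w") as fh:
        fh.write(f"# n_nodes={supra.n_nodes} n_layers={supra.n_layers}\n")
        for r, c in zip(rows, cols):
            fh.write(f"{r}\t{c}\t{supra.mat[r, c]:.17g}\n")
    return path


def read_supra(path: str | Path, labels: list[str] | None = None) -> SupraAdjacency:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        n, b = int(meta["n_nodes"]), int(meta["n_layers"])
        mat = np.zeros((n * b, n * b))
        for line in fh:
            if not line.strip():
                continue
            r, c, w = line.split()
            mat[int(r), int(c)] = mat[int(c), int(r)] = float(w)
    return SupraAdjacency(n_nodes=n, n_layers=b, mat=mat, labels=labels or [])


def hub_table_frame(table: HubTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": table.labels,
            "versatility": table.versatility,
            "z_versatility": table.z_versatility,
            "is_hub": table.is_hub.astype(int),
        }
    )


def dci_frame(result: DCIResult, labels: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": result.candidates,
            "label": [labels[i] for i in result.candidates],
            "dci_raw_pct": result.dci_raw,
            "dci_scaled": result.dci_scaled,
        }
    )


def group_frame(result: GroupResult) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "node": result.candidates,
            "label": [result.labels[i] for i in result.candidates],
            "effect_size": result.effect_size,
            "p_value": result.p_value,
        }
    )
    frame["n_subjects"] = result.n_subjects
    return frame
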