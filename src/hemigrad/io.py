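"""Delimited-text readers/writers for the pipeline's on-disk artefacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, TimeSeriesMatrix
from .embedding import GradientSet


def read_timeseries(path: str | Path, participant_id: str | None = None) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    if participant_id is None:
        participant_id = Path(path).name.removesuffix("_ts.tsv")
    return TimeSeriesMatrix(
        values=df.to_numpy(dtype=float),
        parcel_ids=list(df.columns),
        participant_id=participant_id,
    )


def write_connectivity(conn: ConnectivityMatrix, path: str | Path) -> None:
    pd.DataFrame(conn.values, index=conn.parcel_ids, columns=conn.parcel_ids).to_csv(
        path, sep="\t", index_label=conn.space
    )


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    space = df.index.name if df.index.name in ("pearson_r", "fisher_z") else "pearson_r"
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), parcel_ids=list(df.columns), space=space
    )


def write_gradients(gs: GradientSet, path: str | Path) -> None:
    """Gradient table as TSV (parcel_id + g1..gK) with a JSON sidecar for the
    spectrum and alignment flag."""
    path = Path(path)
    cols = {f"g{k + 1}": gs.coordinates[:, k] for k in range(gs.n_gradients)}
    pd.DataFrame({"parcel_id": list(gs.parcel_ids), **cols}).to_csv(
        path, sep="\t", index=False
    )
    sidecar = {
        "eigenvalues": [float(v) for v in gs.eigenvalues],
        "variance_explained": [float(v) for v in gs.variance_explained],
        "aligned": bool(gs.aligned),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_gradients(path: str | Path) -> GradientSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    gcols = [c for c in df.columns if c.startswith("g") and c[1:].isdigit()]
    gcols = sorted(gcols, key=lambda c: int(c[1:]))
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        eigenvalues = np.asarray(sidecar["eigenvalues"], dtype=float)
        variance = np.asarray(sidecar["variance_explained"], dtype=float)
        aligned = bool(sidecar["aligned"])
    else:
        eigenvalues = np.full(len(gcols), np.nan)
        variance = np.full(len(gcols), np.nan)
        aligned = False
    return GradientSet(
        coordinates=df[gcols].to_numpy(dtype=float),
        eigenvalues=eigenvalues,
        variance_explained=variance,
        parcel_ids=[str(p) for p in df["parcel_id"]],
        aligned=aligned,
    )


def write_transform(transform: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, transform, delimiter="\t")
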