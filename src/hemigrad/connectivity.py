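"""Per-participant and group-averaged functional connectivity matrices.

Pearson correlation between parcel time-series, Fisher-Z transformed before
averaging. The group matrix stays in Fisher-Z space for embedding; the
diagonal is set to 0 after the transform (self-connections carry no
information and would otherwise dominate row sparsification).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

_SYM_TOL = 1e-10
_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """T x P parcel time-series for one participant (columns follow the atlas)."""

    values: np.ndarray
    parcel_ids: Sequence[str]
    participant_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("time-series must be a 2-D T x P matrix")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if v.shape[1] != len(self.parcel_ids):
            raise ValueError("parcel_ids must match the number of columns")
        if not np.isfinite(v).all():
            raise ValueError("time-series contains non-finite values")


@dataclass(frozen=True)
class ConnectivityMatrix:
    """P x P symmetric connectivity; ``space`` is 'pearson_r' or 'fisher_z'."""

    values: np.ndarray
    parcel_ids: Sequence[str]
    space: str = "pearson_r"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity must be square")
        if v.shape[0] != len(self.parcel_ids):
            raise ValueError("parcel_ids must match matrix size")
        if self.space not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown space {self.space!r}")
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise ValueError("connectivity matrix is not symmetric")
        if self.space == "pearson_r":
            if np.abs(v).max() > 1 + 1e-12:
                raise ValueError("pearson_r entries must lie in [-1, 1]")
            if np.abs(np.diag(v) - 1).max() > 1e-12:
                raise ValueError("pearson_r diagonal must be 1")


def pearson_connectivity(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of parcel time-series."""
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [ts.parcel_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance parcel(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(ts.parcel_ids), space="pearson_r")


def fisher_z(conn: ConnectivityMatrix) -> ConnectivityMatrix:
    """atanh transform of off-diagonal correlations; diagonal set to 0.

    Off-diagonal |r| = 1 (duplicate parcels) is clipped to 1 - 1e-7 with a
    logged warning rather than producing infinities.
    """
    if conn.space != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    r = conn.values.copy()
    np.fill_diagonal(r, 0.0)
    extreme = np.abs(r) > _CLIP
    if extreme.any():
        log.warning(
            "clipping %d off-diagonal |r|~1 entries before atanh", extreme.sum()
        )
        r = np.clip(r, -_CLIP, _CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, list(conn.parcel_ids), space="fisher_z")


def group_average_connectivity(
    matrices: Sequence[ConnectivityMatrix],
) -> ConnectivityMatrix:
    """Entrywise mean of Fisher-Z matrices sharing one parcel ordering."""
    if not matrices:
        raise ValueError("need at least one matrix to average")
    ref = list(matrices[0].parcel_ids)
    for m in matrices:
        if m.space != "fisher_z":
            raise ValueError("group averaging expects fisher_z matrices")
        if list(m.parcel_ids) != ref:
            raise ValueError("parcel orderings differ between matrices")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(mean, ref, space="fisher_z")


def permute_parcels(
    conn: ConnectivityMatrix, order: Sequence[int]
) -> ConnectivityMatrix:
    """Consistently reorder rows/columns (utility for equivariance checks)."""
    idx = np.asarray(order)
    return replace(
        conn,
        values=conn.values[np.ix_(idx, idx)],
        parcel_ids=[conn.parcel_ids[i] for i in idx],
    )
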