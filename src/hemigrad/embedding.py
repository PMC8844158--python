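"""Connectivity gradients by diffusion-map embedding.

Pipeline: per-row sparsification of the (Fisher-Z) connectivity matrix
(top 10% of connections retained by default), normalized-angle affinity
between the sparsified rows, then diffusion-map embedding of the affinity:

    W' = D^-alpha W D^-alpha          (anisotropic normalization, alpha=0.5)
    P  = D'^-1 W'                     (row-stochastic transition operator)

The eigenvectors of P (computed through the conjugate symmetric operator
D'^-1/2 W' D'^-1/2) give the gradients; the trivial constant eigenvector at
eigenvalue 1 is dropped. With diffusion time t > 0 gradient k is psi_k *
lambda_k^t; the default t = 0 uses the regularized multi-scale weighting
lambda_k / (1 - lambda_k). Gradients are ordered by eigenvalue and
sign-fixed (largest-magnitude entry positive) so repeated runs agree
exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph

from .connectivity import ConnectivityMatrix

log = logging.getLogger(__name__)

_SYM_TOL = 1e-10


@dataclass(frozen=True)
class RowSparseMatrix:
    """Row-sparsified connectivity (generally asymmetric)."""

    values: np.ndarray
    parcel_ids: Sequence[str]


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric normalized-angle affinity in [0, 1], zero diagonal."""

    values: np.ndarray
    parcel_ids: Sequence[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise ValueError("affinity matrix is not symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("affinity entries must lie in [0, 1]")


@dataclass(frozen=True)
class GradientSet:
    """P x K gradient coordinates with their eigenvalue spectrum.

    Column k is gradient k+1; ``eigenvalues`` are the nontrivial transition
    operator eigenvalues (nonincreasing), ``variance_explained`` their share
    of the retained spectrum.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    parcel_ids: Sequence[str]
    aligned: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        e = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "coordinates", c)
        object.__setattr__(self, "eigenvalues", e)
        object.__setattr__(
            self, "variance_explained", np.asarray(self.variance_explained, float)
        )
        if c.ndim != 2:
            raise ValueError("coordinates must be P x K")
        if c.shape[0] != len(self.parcel_ids):
            raise ValueError("parcel_ids must match coordinate rows")
        if c.shape[1] > c.shape[0] - 1:
            raise ValueError("cannot retain more than P-1 gradients")
        if e.shape != (c.shape[1],):
            raise ValueError("one eigenvalue per gradient required")
        if np.any(np.diff(e) > 1e-10):
            raise ValueError("eigenvalues must be nonincreasing")
        if e.size and e.min() < -1e-10:
            log.debug("negative transition-operator eigenvalues retained")

    @property
    def n_gradients(self) -> int:
        return self.coordinates.shape[1]

    def gradient(self, index: int) -> np.ndarray:
        """1-based accessor: gradient(1) is the principal gradient."""
        if not 1 <= index <= self.n_gradients:
            raise IndexError(f"gradient index {index} out of range")
        return self.coordinates[:, index - 1]


def sparsify_rows(
    conn: ConnectivityMatrix, sparsity: float = 0.9
) -> RowSparseMatrix:
    """Keep the ceil((1-sparsity)*P) largest entries of each row, zero the
    rest. Ties at the threshold are broken by first index."""
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    v = conn.values
    p = v.shape[0]
    keep = math.ceil((1.0 - sparsity) * p)
    out = np.zeros_like(v)
    # stable sort on descending values: equal entries keep first-index order
    order = np.argsort(-v, axis=1, kind="stable")[:, :keep]
    rows = np.arange(p)[:, None]
    out[rows, order] = v[rows, order]
    return RowSparseMatrix(out, list(conn.parcel_ids))


def normalized_angle_affinity(
    conn: Union[ConnectivityMatrix, RowSparseMatrix],
) -> AffinityMatrix:
    """a(i,j) = 1 - arccos(cosine(row_i, row_j)) / pi on the (sparsified)
    connectivity rows; diagonal zeroed per the embedding convention."""
    v = conn.values
    norms = np.linalg.norm(v, axis=1)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        names = [conn.parcel_ids[i] for i in dead[:5]]
        raise ValueError(
            f"all-zero connectivity row(s) (over-sparsified input): {names}"
        )
    cos = (v @ v.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    a = 1.0 - np.arccos(cos) / np.pi
    # cosine is symmetric in its arguments even on asymmetric sparsified rows
    assert np.abs(a - a.T).max() <= 1e-9, "kernel output unexpectedly asymmetric"
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)  # clamp float round-off at 0 and 1
    np.fill_diagonal(a, 0.0)
    return AffinityMatrix(a, list(conn.parcel_ids))


def diffusion_embed(
    aff: AffinityMatrix,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity.

    Raises if the affinity graph is disconnected (reporting component sizes)
    or if ``n_components >= P``.
    """
    w = np.asarray(aff.values, dtype=float)
    p = w.shape[0]
    if n_components >= p:
        raise ValueError(f"n_components must be < {p}")
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(w > 0), directed=False
    )
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"affinity graph has {n_comp} connected components (sizes {sizes})"
        )

    d = w.sum(axis=1)
    d_alpha = d ** (-alpha)
    lw = w * d_alpha[:, None] * d_alpha[None, :]
    d2 = lw.sum(axis=1)
    dis = 1.0 / np.sqrt(d2)
    ms = lw * dis[:, None] * dis[None, :]
    ms = (ms + ms.T) / 2.0

    evals, evecs = scipy.linalg.eigh(ms)
    sel = slice(p - (n_components + 1), p)
    evals = evals[sel][::-1]
    evecs = evecs[:, sel][:, ::-1]

    v0 = evecs[:, 0]
    if v0[np.argmax(np.abs(v0))] < 0:  # stationary vector, make positive
        evecs = -evecs
    psi = evecs / evecs[:, [0]]

    lam = evals[1:]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    coords = psi[:, 1:] * scale[None, :]

    # deterministic sign: largest-|entry| positive per gradient
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]

    # share of the retained spectrum; negative tail (possible for a generic
    # symmetric affinity) carries no variance
    pos = np.clip(lam, 0.0, None)
    total = pos.sum()
    var_exp = pos / total if total != 0 else np.full_like(lam, np.nan)
    return GradientSet(
        coordinates=coords,
        eigenvalues=lam,
        variance_explained=var_exp,
        parcel_ids=list(aff.parcel_ids),
        aligned=False,
    )


def embed_connectivity(
    conn: ConnectivityMatrix,
    n_components: int = 10,
    sparsity: float = 0.9,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Convenience wrapper: sparsify -> normalized-angle kernel -> embed."""
    return diffusion_embed(
        normalized_angle_affinity(sparsify_rows(conn, sparsity)),
        n_components=n_components,
        alpha=alpha,
        diffusion_time=diffusion_time,
    )


def permute_gradient_parcels(gs: GradientSet, order: Sequence[int]) -> GradientSet:
    idx = np.asarray(order)
    return replace(
        gs,
        coordinates=gs.coordinates[idx],
        parcel_ids=[gs.parcel_ids[i] for i in idx],
    )
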