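"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's code paths: loop-built operators,
the non-symmetric eigensolver, and naive per-element formulas.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def diffusion_map_reference(
    w: np.ndarray,
    n_components: int,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dense brute-force diffusion map: loop-built anisotropic normalization,
    non-symmetric eigendecomposition of the row-stochastic operator."""
    p = w.shape[0]
    d = np.array([w[i].sum() for i in range(p)])
    lw = np.empty_like(w, dtype=float)
    for i in range(p):
        for j in range(p):
            lw[i, j] = w[i, j] / (d[i] ** alpha * d[j] ** alpha)
    d2 = np.array([lw[i].sum() for i in range(p)])
    trans = lw / d2[:, None]

    evals, evecs = scipy.linalg.eig(trans)
    order = np.argsort(evals.real)[::-1]
    evals = evals.real[order]
    evecs = evecs[:, order].real

    # move to the symmetric-operator basis and unit-normalize, matching the
    # scaling convention of an orthonormal symmetric eigendecomposition
    v = np.sqrt(d2)[:, None] * evecs
    v = v / np.linalg.norm(v, axis=0)
    if v[np.argmax(np.abs(v[:, 0])), 0] < 0:
        v[:, 0] = -v[:, 0]
    psi = v / v[:, [0]]

    lam = evals[1 : n_components + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    coords = psi[:, 1 : n_components + 1] * scale[None, :]
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    return coords, lam


def pearson_reference(x: np.ndarray) -> np.ndarray:
    """Entrywise covariance / SD formula, one pair at a time."""
    t, p = x.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(p):
            xi = x[:, i] - x[:, i].mean()
            xj = x[:, j] - x[:, j].mean()
            out[i, j] = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
    return out


def sparsify_reference(values: np.ndarray, sparsity: float) -> np.ndarray:
    """Per-row sort-based top-k retention with first-index tie-breaking."""
    import math

    p = values.shape[1]
    keep = math.ceil((1 - sparsity) * p)
    out = np.zeros_like(values)
    for i in range(values.shape[0]):
        ranked = sorted(range(p), key=lambda j: (-values[i, j], j))
        for j in ranked[:keep]:
            out[i, j] = values[i, j]
    return out


def signflip_enumeration_pvalue(d: np.ndarray) -> float:
    """Exhaustive two-sided sign-flip p for the mean of paired differences."""
    import itertools

    n = d.size
    obs = abs(d.mean())
    count = 0
    total = 0
    for signs in itertools.product([1.0, -1.0], repeat=n):
        total += 1
        if abs(np.dot(signs, d) / n) >= obs - 1e-12:
            count += 1
    return count / total


def random_affinity(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric nonnegative affinity with zero diagonal."""
    a = rng.uniform(0.05, 1.0, size=(p, p))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a
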