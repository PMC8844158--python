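"""Procrustes alignment of gradient sets and similarity quantification.

Default is rotation/reflection only — no centering, no scaling — so gradient
magnitudes consumed by the lateralization statistic are preserved; uniform
scaling is available behind a flag. Column matching is by index after the
rotation (the orthogonal transform absorbs sign flips and reordering of
individual-level gradients relative to the template).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.stats

from .embedding import GradientSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentResult:
    rotated: GradientSet
    transform: np.ndarray  # K x K orthogonal (reflections permitted)
    scale: float
    disparity: float  # sum of squared residuals to the target

    def __post_init__(self) -> None:
        q = np.asarray(self.transform, dtype=float)
        object.__setattr__(self, "transform", q)
        k = q.shape[0]
        if q.shape != (k, k) or np.abs(q.T @ q - np.eye(k)).max() > 1e-8:
            raise ValueError("transform must be orthogonal")
        if self.disparity < -1e-12:
            raise ValueError("disparity must be nonnegative")


def _check_compatible(a: GradientSet, b: GradientSet) -> None:
    if list(a.parcel_ids) != list(b.parcel_ids):
        raise ValueError("gradient sets cover different parcels")
    if a.n_gradients != b.n_gradients:
        raise ValueError(
            f"gradient count mismatch: {a.n_gradients} vs {b.n_gradients}"
        )


def procrustes_align(
    source: GradientSet, target: GradientSet, with_scaling: bool = False
) -> AlignmentResult:
    """Orthogonal (optionally scaled) Procrustes: argmin_Q ||target - source Q s||."""
    _check_compatible(source, target)
    a = source.coordinates
    b = target.coordinates
    q, _ = scipy.linalg.orthogonal_procrustes(a, b)
    s = 1.0
    if with_scaling:
        denom = np.sum(a * a)
        s = float(np.trace(b.T @ a @ q) / denom) if denom > 0 else 1.0
    rotated = a @ q * s
    disparity = float(np.sum((b - rotated) ** 2))
    return AlignmentResult(
        rotated=replace(source, coordinates=rotated, aligned=True),
        transform=q,
        scale=s,
        disparity=disparity,
    )


def iterative_group_align(
    individuals: Sequence[GradientSet],
    template: GradientSet,
    n_iterations: int = 10,
    with_scaling: bool = False,
    fixed_template: bool = False,
) -> list[AlignmentResult]:
    """Align every individual to a template, then re-align to the mean of the
    aligned sets for the remaining iterations (or to the fixed template when
    ``fixed_template=True``)."""
    if not individuals:
        raise ValueError("need at least one gradient set to align")
    for g in individuals:
        _check_compatible(g, template)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")

    reference = template
    results: list[AlignmentResult] = []
    for _ in range(n_iterations):
        results = [
            procrustes_align(g, reference, with_scaling=with_scaling)
            for g in individuals
        ]
        if not fixed_template:
            mean_coords = np.mean([r.rotated.coordinates for r in results], axis=0)
            reference = replace(template, coordinates=mean_coords, aligned=True)
    return results


def spearman_gradient_similarity(a: GradientSet, b: GradientSet) -> np.ndarray:
    """Spearman rho per matched gradient column; NaN (with a warning) for a
    constant column, where the rank correlation is undefined."""
    if list(a.parcel_ids) != list(b.parcel_ids):
        raise ValueError("gradient sets cover different parcels")
    k = min(a.n_gradients, b.n_gradients)
    rhos = np.empty(k)
    for j in range(k):
        x = a.coordinates[:, j]
        y = b.coordinates[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            log.warning("constant gradient column %d: similarity undefined", j + 1)
            rhos[j] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhos[j] = scipy.stats.spearmanr(x, y).statistic
    return rhos
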