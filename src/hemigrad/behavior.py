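"""Behavioural scoring and individual-differences regressions.

Condition-level performance is collapsed into efficiency scores
(-(RT / accuracy), higher = better, controlling speed-accuracy trade-offs),
reduced to factor scores by PCA with varimax rotation (Kaiser criterion),
cleaned by z-score outlier imputation, and related to per-network hemispheric
difference scores with one OLS model per network (all explanatory variables
entered jointly, standardized betas reported).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.multivariate.factor_rotation import rotate_factors

log = logging.getLogger(__name__)


def efficiency_score(rt, accuracy):
    """-(rt / accuracy): penalizes both slowness and errors. Vectorized."""
    rt = np.asarray(rt, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if np.any(accuracy <= 0):
        raise ValueError("accuracy must be > 0 (flag the condition for exclusion)")
    if np.any(rt <= 0):
        raise ValueError("response times must be > 0")
    out = -(rt / accuracy)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FactorSolution:
    loadings: pd.DataFrame  # conditions x factors
    scores: pd.DataFrame  # participants x factors
    eigenvalues: np.ndarray  # all PCA eigenvalues, descending
    variance_explained: np.ndarray  # fraction per retained factor
    n_retained: int


def _varimax_kaiser(loadings: np.ndarray) -> np.ndarray:
    """Varimax rotation with Kaiser (row) normalization."""
    h = np.sqrt((loadings**2).sum(axis=1))
    h[h == 0] = 1.0
    rotated, _ = rotate_factors(loadings / h[:, None], "varimax")
    return rotated * h[:, None]


def pca_varimax(condition_scores: pd.DataFrame) -> FactorSolution:
    """PCA on the correlation matrix; retain eigenvalues > 1 (Kaiser);
    varimax-rotate when two or more components survive. Factor scores use
    the regression method."""
    x = condition_scores.to_numpy(dtype=float)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 participants")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(condition_scores.columns[sd == 0])
        raise ValueError(f"constant condition column(s): {bad}")
    if n < k:
        log.warning("fewer participants (%d) than conditions (%d)", n, k)
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    if np.linalg.matrix_rank(corr) < k:
        raise ValueError("singular correlation matrix")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_retained = int((evals > 1.0).sum())
    if n_retained == 0:
        raise ValueError("no component passes the Kaiser criterion")

    loadings = evecs[:, :n_retained] * np.sqrt(evals[:n_retained])
    if n_retained >= 2:
        loadings = _varimax_kaiser(loadings)
    # deterministic sign: dominant loading positive per factor
    for j in range(n_retained):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    # order factors by explained variance after rotation
    var = (loadings**2).sum(axis=0)
    order = np.argsort(var)[::-1]
    loadings = loadings[:, order]
    var = var[order]

    weights = np.linalg.solve(corr, loadings)  # regression-method weights
    scores = z @ weights
    names = [f"factor{j + 1}" for j in range(n_retained)]
    return FactorSolution(
        loadings=pd.DataFrame(loadings, index=condition_scores.columns, columns=names),
        scores=pd.DataFrame(scores, index=condition_scores.index, columns=names),
        eigenvalues=evals,
        variance_explained=var / k,
        n_retained=n_retained,
    )


def zscore_impute(scores, threshold: float = 2.5) -> np.ndarray:
    """z-score, then replace |z| > threshold by 0 (the mean of a z-scored
    variable). The replacement count is logged."""
    x = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; z-scores undefined")
    z = (x - x.mean()) / sd
    outliers = np.abs(z) > threshold
    if outliers.any():
        log.info("imputing %d outlier(s) beyond |z|=%g", outliers.sum(), threshold)
    z[outliers] = 0.0
    return z


def condition_contrast(
    condition_scores: pd.DataFrame,
    positive: Sequence[str],
    negative: Sequence[str],
) -> pd.Series:
    """Mean difference between two sets of condition columns, per
    participant — an alternative EV construction for contrasts such as
    modality (pictures vs words) or strength of association (weak vs
    strong)."""
    for col in list(positive) + list(negative):
        if col not in condition_scores.columns:
            raise ValueError(f"unknown condition column {col!r}")
    return (
        condition_scores[list(positive)].mean(axis=1)
        - condition_scores[list(negative)].mean(axis=1)
    )


@dataclass(frozen=True)
class RegressionResult:
    network: str
    predictor: str
    beta: float  # standardized
    p: float
    n: int


def regress_difference_on_behavior(
    diffs: pd.DataFrame,
    behavior: pd.DataFrame,
    networks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One OLS fit per network: difference score on all EVs jointly.

    ``behavior`` has participant_id plus standardized EV columns. Only the
    networks in ``networks`` (e.g. those passing the permutation screen) are
    modelled; default is every network present. Participants missing from
    either table are dropped with a log entry.
    """
    ev_cols = [c for c in behavior.columns if c != "participant_id"]
    if not ev_cols:
        raise ValueError("behaviour table has no explanatory variables")
    if networks is None:
        networks = list(dict.fromkeys(diffs["network"]))
    rows = []
    for net in networks:
        sub = diffs[diffs["network"] == net][["participant_id", "diff"]]
        if sub.empty:
            raise ValueError(f"no difference scores for network {net!r}")
        merged = sub.merge(behavior, on="participant_id", how="inner")
        dropped = len(sub) + len(behavior) - 2 * len(merged)
        if dropped:
            log.info("network %s: %d unmatched participant rows dropped", net, dropped)
        y = merged["diff"].to_numpy(dtype=float)
        x = merged[ev_cols].to_numpy(dtype=float)
        n = len(y)
        if n <= len(ev_cols) + 1:
            raise ValueError(f"too few matched participants for network {net!r}")
        sd_x = x.std(axis=0, ddof=1)
        if np.any(sd_x == 0):
            bad = [ev_cols[i] for i in np.flatnonzero(sd_x == 0)]
            raise ValueError(f"constant EV column(s): {bad}")
        xz = (x - x.mean(axis=0)) / sd_x
        if np.linalg.matrix_rank(xz) < xz.shape[1]:
            cmat = np.corrcoef(xz, rowvar=False)
            pairs = [
                (ev_cols[i], ev_cols[j])
                for i in range(len(ev_cols))
                for j in range(i + 1, len(ev_cols))
                if abs(cmat[i, j]) > 1 - 1e-10
            ]
            raise ValueError(f"rank-deficient design; collinear EVs: {pairs}")
        sd_y = y.std(ddof=1)
        if sd_y == 0:
            raise ValueError(f"constant difference scores for network {net!r}")
        yz = (y - y.mean()) / sd_y
        fit = sm.OLS(yz, sm.add_constant(xz)).fit()
        for j, name in enumerate(ev_cols):
            rows.append(
                RegressionResult(
                    network=net,
                    predictor=name,
                    beta=float(fit.params[j + 1]),
                    p=float(fit.pvalues[j + 1]),
                    n=n,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
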