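"""Network-level hemispheric differences in gradient position, with inference.

Per participant, the chosen gradient is min-max normalized to 0-100 over all
parcels of both hemispheres jointly (normalizing per hemisphere would erase
the global offset the analysis is after), averaged within each network x
hemisphere cell, and the left-minus-right difference per network is the
central statistic. Inference:

* a global paired t-test of the per-participant hemisphere means;
* a 2 x N-network repeated-measures ANOVA with Greenhouse-Geisser correction
  and an optional per-participant covariate of no interest;
* per-network sign-flip permutation tests (exchangeable hemisphere labels
  under the null), Bonferroni-corrected across networks;
* paired t-tests on within-hemisphere gradient distances between network
  pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .atlas import ParcelAtlas
from .embedding import GradientSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization and summaries
# ---------------------------------------------------------------------------

def minmax_normalize(grad: GradientSet, gradient_index: int = 1) -> np.ndarray:
    """Map one gradient column to 0-100 over all parcels jointly."""
    v = grad.gradient(gradient_index)
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError(f"gradient {gradient_index} is constant; cannot normalize")
    return 100.0 * (v - lo) / (hi - lo)


def summarize_networks(
    normalized_values: np.ndarray,
    atlas: ParcelAtlas,
    participant_id: str,
    gradient_index: int = 1,
) -> pd.DataFrame:
    """Unweighted mean of normalized parcel values per network x hemisphere.

    A network with parcels in only one hemisphere yields a row for that
    hemisphere only (warning logged; its difference score is undefined and
    later excluded).
    """
    v = np.asarray(normalized_values, dtype=float)
    if v.shape != (atlas.n_parcels,):
        raise ValueError("one value per atlas parcel required")
    df = atlas.table.assign(value=v)
    rows = []
    for net in atlas.networks:
        present = set(df.loc[df["network"] == net, "hemisphere"])
        if len(present) < 2:
            log.warning(
                "network %s has parcels in only one hemisphere (%s)",
                net, sorted(present),
            )
        for hemi in sorted(present):
            cell = df[(df["network"] == net) & (df["hemisphere"] == hemi)]
            rows.append(
                {
                    "participant_id": participant_id,
                    "network": net,
                    "hemisphere": hemi,
                    "mean_gradient": float(cell["value"].mean()),
                    "gradient_index": gradient_index,
                }
            )
    return pd.DataFrame(rows)


def cohort_network_summary(
    gradients: Mapping[str, GradientSet],
    atlas: ParcelAtlas,
    gradient_index: int = 1,
) -> pd.DataFrame:
    """Min-max normalize and summarize every participant's gradient set."""
    parts = []
    for pid, gs in gradients.items():
        if list(gs.parcel_ids) != atlas.parcel_ids:
            raise ValueError(f"parcel ordering mismatch for participant {pid}")
        values = minmax_normalize(gs, gradient_index)
        parts.append(summarize_networks(values, atlas, pid, gradient_index))
    return pd.concat(parts, ignore_index=True)


def hemispheric_difference(summary: pd.DataFrame) -> pd.DataFrame:
    """LH - RH network means per participant (tidy: participant_id, network,
    diff). Networks missing a hemisphere are skipped with a warning."""
    wide = summary.pivot_table(
        index=["participant_id", "network"],
        columns="hemisphere",
        values="mean_gradient",
        aggfunc="first",
    ).reindex(columns=["L", "R"])
    missing = wide.index[wide.isna().any(axis=1)].get_level_values("network")
    for net in sorted(set(missing)):
        log.warning("network %s missing a hemisphere; difference skipped", net)
    wide = wide.dropna()
    return (wide["L"] - wide["R"]).rename("diff").reset_index()


def zscore_difference_map(diffs: pd.DataFrame) -> pd.Series:
    """Group-mean difference per network, standardized across networks
    (population SD), highlighting the networks with the most extreme
    hemispheric differences."""
    means = diffs.groupby("network", sort=False)["diff"].mean()
    if len(means) < 3:
        raise ValueError("need at least 3 networks to z-score the map")
    sd = means.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across network means; map undefined")
    return (means - means.mean()) / sd


# ---------------------------------------------------------------------------
# global test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalHemisphereResult:
    t: float
    df: int
    p: float
    mean_left: float
    mean_right: float
    frac_left_higher: float
    n: int


def global_hemisphere_test(summary: pd.DataFrame) -> GlobalHemisphereResult:
    """Paired t-test of per-participant global hemisphere means (mean over
    network means), plus the fraction of participants with L > R."""
    hemi_means = summary.pivot_table(
        index="participant_id", columns="hemisphere", values="mean_gradient",
        aggfunc="mean",
    ).dropna()
    n = len(hemi_means)
    if n < 2:
        raise ValueError("need at least 2 participants for a paired t-test")
    left = hemi_means["L"].to_numpy()
    right = hemi_means["R"].to_numpy()
    d = left - right
    if d.std(ddof=1) == 0:
        if np.allclose(d, 0):
            t, p = 0.0, 1.0
        else:
            log.warning("zero-variance nonzero hemisphere difference; p -> 0")
            t, p = math.inf * np.sign(d.mean()), 0.0
    else:
        res = scipy.stats.ttest_rel(left, right)
        t, p = float(res.statistic), float(res.pvalue)
    return GlobalHemisphereResult(
        t=t,
        df=n - 1,
        p=p,
        mean_left=float(left.mean()),
        mean_right=float(right.mean()),
        frac_left_higher=float((d > 0).mean()),
        n=n,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(p: int) -> np.ndarray:
    """p x (p-1) orthonormal contrast matrix (columns sum to zero)."""
    h = np.zeros((p, p - 1))
    for j in range(1, p):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _within_effect(
    t_mat: np.ndarray, covariate: np.ndarray | None
) -> tuple[float, float, float, float, float, float, float]:
    """Univariate RM-ANOVA F for one within effect from its contrast scores.

    ``t_mat`` is n x q (subjects x contrast variables). Returns
    (F, df1, df2, eps, p_gg, p_unc, partial eta squared).
    """
    n, q = t_mat.shape
    lost = 0
    if covariate is not None:
        x = covariate - covariate.mean()
        ssx = float(x @ x)
        if ssx > 0:
            beta = (x @ t_mat) / ssx
            t_mat = t_mat - np.outer(x, beta)
            lost = 1
    tbar = t_mat.mean(axis=0)
    ss_eff = n * float(tbar @ tbar)
    resid = t_mat - tbar
    ss_err = float(np.sum(resid * resid))
    df1 = float(q)
    df2 = float(q * (n - 1 - lost))
    if ss_err == 0:
        return math.inf, df1, df2, 1.0, 0.0, 0.0, 1.0
    f_stat = (ss_eff / df1) / (ss_err / df2)
    # Greenhouse-Geisser epsilon from the contrast-score covariance
    s = np.cov(t_mat, rowvar=False).reshape(q, q)
    eps = float(np.trace(s) ** 2 / (q * np.sum(s * s)))
    eps = min(1.0, max(eps, 1.0 / q))
    p_unc = float(scipy.stats.f.sf(f_stat, df1, df2))
    p_gg = float(scipy.stats.f.sf(f_stat, eps * df1, eps * df2))
    peta = ss_eff / (ss_eff + ss_err)
    return f_stat, df1, df2, eps, p_gg, p_unc, peta


def rm_anova_hemisphere_network(
    summary: pd.DataFrame, covariate: pd.Series | None = None
) -> pd.DataFrame:
    """2 (hemisphere) x N (network) within-subject ANOVA on network means.

    ``covariate`` (indexed by participant_id; e.g. each participant's global
    L-R value as a covariate of no interest) is partialled out of every
    within-subject contrast, charging one error df per contrast variable.
    Returns one row per effect with Greenhouse-Geisser-corrected p values and
    partial eta squared.
    """
    networks = list(dict.fromkeys(summary["network"]))
    wide = summary.pivot_table(
        index="participant_id",
        columns=["hemisphere", "network"],
        values="mean_gradient",
        aggfunc="first",
    )
    expected = pd.MultiIndex.from_product([["L", "R"], networks])
    missing = [c for c in expected if c not in wide.columns]
    if missing or wide.isna().any().any():
        bad = missing + list(wide.columns[wide.isna().any()])
        raise ValueError(f"incomplete 2 x network design; missing cells: {bad}")
    y = wide[expected].to_numpy(dtype=float)  # n x (2*m), hemisphere-major
    n = y.shape[0]
    m = len(networks)
    if n < 3:
        raise ValueError("need at least 3 participants")

    cov = None
    if covariate is not None:
        cov = covariate.reindex(wide.index)
        if cov.isna().any():
            raise ValueError("covariate missing for some participants")
        cov = cov.to_numpy(dtype=float)

    c2 = np.array([[1.0], [-1.0]]) / np.sqrt(2.0)
    ones2 = np.ones((2, 1)) / np.sqrt(2.0)
    cm = _orthonormal_contrasts(m)
    ones_m = np.ones((m, 1)) / np.sqrt(m)
    effects = {
        "hemisphere": np.kron(c2, ones_m),
        "network": np.kron(ones2, cm),
        "hemisphere:network": np.kron(c2, cm),
    }
    rows = []
    for name, c in effects.items():
        f_stat, df1, df2, eps, p_gg, p_unc, peta = _within_effect(y @ c, cov)
        rows.append(
            {
                "effect": name,
                "F": f_stat,
                "df1": df1,
                "df2": df2,
                "eps_gg": eps,
                "p_gg": p_gg,
                "p_uncorrected": p_unc,
                "partial_eta_sq": peta,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    network: str
    observed_mean_diff: float
    p_uncorrected: float
    p_bonferroni: float
    significant: bool
    n_resamples: int
    exhaustive: bool


def _signflip_pvalue(
    d: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> tuple[float, bool]:
    """Two-sided sign-flip p for the mean of paired differences ``d``.

    All 2^n sign patterns are enumerated when that is no more work than the
    requested resamples (exact p = count / 2^n, the identity flip included);
    otherwise Monte-Carlo with the add-one convention (1+count)/(B+1).
    """
    n = d.size
    obs = abs(d.mean())
    tol = 1e-12 * max(1.0, obs)
    if n <= 30 and 2**n <= n_resamples:
        signs = np.array(
            np.meshgrid(*([[1.0, -1.0]] * n), indexing="ij")
        ).reshape(n, -1).T
        null = np.abs(signs @ d) / n
        return float((null >= obs - tol).mean()), True
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    null = np.abs(signs @ d) / n
    count = int((null >= obs - tol).sum())
    return (1 + count) / (n_resamples + 1), False


def _bootstrap_pvalue(
    d: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> float:
    """Two-sided p from a participant bootstrap of mean-centred differences."""
    centred = d - d.mean()
    obs = abs(d.mean())
    n = d.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    null = np.abs(centred[idx].mean(axis=1))
    count = int((null >= obs - 1e-12 * max(1.0, obs)).sum())
    return (1 + count) / (n_resamples + 1)


def permutation_network_test(
    diffs: pd.DataFrame,
    n_resamples: int = 5000,
    seed: int | None = 0,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    scheme: str = "signflip",
) -> pd.DataFrame:
    """Per-network resampling test of the mean LH-RH difference.

    With the default ``scheme='signflip'``: under H0 the hemisphere labels
    are exchangeable within participant, so each participant's difference
    score is symmetric about 0; the null is built by random (or exhaustive)
    sign flips. ``scheme='bootstrap'`` instead resamples participants with
    replacement from the mean-centred differences. Bonferroni correction
    spans ``n_comparisons`` (default: the number of networks tested).
    """
    if scheme not in ("signflip", "bootstrap"):
        raise ValueError(f"unknown scheme {scheme!r}")
    networks = list(dict.fromkeys(diffs["network"]))
    counts = diffs.groupby("network")["participant_id"].nunique()
    if counts.min() < 5:
        raise ValueError("need at least 5 participants per network")
    if n_resamples < 100:
        log.warning(
            "n_resamples=%d gives p-value resolution %.3f",
            n_resamples, 1 / (n_resamples + 1),
        )
    if n_comparisons is None:
        n_comparisons = len(networks)
    rng = np.random.default_rng(seed)
    rows = []
    for net in networks:
        d = diffs.loc[diffs["network"] == net, "diff"].to_numpy(dtype=float)
        if scheme == "signflip":
            p, exact = _signflip_pvalue(d, n_resamples, rng)
        else:
            p, exact = _bootstrap_pvalue(d, n_resamples, rng), False
        p_bonf = min(1.0, n_comparisons * p)
        rows.append(
            PermutationResult(
                network=net,
                observed_mean_diff=float(d.mean()),
                p_uncorrected=p,
                p_bonferroni=p_bonf,
                significant=p_bonf < alpha,
                n_resamples=n_resamples,
                exhaustive=exact,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# network-pair gradient distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairDistanceResult:
    network_a: str
    network_b: str
    mean_left: float
    sd_left: float
    mean_right: float
    sd_right: float
    t: float
    df: int
    p: float
    p_corrected: float
    n: int


def network_pair_distance_test(
    summary: pd.DataFrame,
    network_a: str,
    network_b: str,
    n_comparisons: int = 1,
) -> PairDistanceResult:
    """Compare the within-hemisphere gradient distance (mean_b - mean_a)
    between hemispheres with a paired t-test."""
    wide = summary.pivot_table(
        index="participant_id",
        columns=["network", "hemisphere"],
        values="mean_gradient",
        aggfunc="first",
    )
    for net in (network_a, network_b):
        for hemi in ("L", "R"):
            if (net, hemi) not in wide.columns:
                raise ValueError(f"network {net!r} missing hemisphere {hemi!r}")
    dist = {
        h: (wide[(network_b, h)] - wide[(network_a, h)]).dropna() for h in "LR"
    }
    joined = pd.concat(dist, axis=1).dropna()
    n = len(joined)
    res = scipy.stats.ttest_rel(joined["L"], joined["R"])
    p = float(res.pvalue)
    return PairDistanceResult(
        network_a=network_a,
        network_b=network_b,
        mean_left=float(joined["L"].mean()),
        sd_left=float(joined["L"].std(ddof=1)),
        mean_right=float(joined["R"].mean()),
        sd_right=float(joined["R"].std(ddof=1)),
        t=float(res.statistic),
        df=n - 1,
        p=p,
        p_corrected=min(1.0, n_comparisons * p),
        n=n,
    )
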