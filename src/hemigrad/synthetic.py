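"""Synthetic resting-state cohorts with a planted 1-D connectivity gradient.

The generator emulates the statistical structure the lateralization analysis
assumes, so the full pipeline can be exercised without access to scan data:

* every parcel carries a latent coordinate ``g`` in [0, 1] (its planted
  position on the principal gradient); inter-parcel correlation decays as
  ``exp(-|g_i - g_j| / tau)``, an Ornstein-Uhlenbeck kernel that is positive
  semidefinite for any coordinate set and whose leading nontrivial diffusion
  eigenvector orders parcels by ``g``;
* each network has a population left-minus-right coordinate offset; each
  participant draws their own offset from ``Normal(mean, sd)`` and it is
  applied to the left-hemisphere parcels only, so LH-RH remains interpretable
  as the planted offset;
* behavioural scores are standard-normal, optionally coupled to the
  participant's planted asymmetry in one target network with a specified
  correlation.

By default the networks are spread evenly along [0, 1] in canonical
principal-gradient order (visual networks near the bottom, default-mode
networks near the apex), and the parcels of a network tile a small
neighbourhood of the network's position (``within_network_spread``) rather
than coinciding exactly — mirroring the within-network heterogeneity of real
parcellations, and keeping the sparsified affinity graph a single ordered
chain rather than a set of duplicate-row cliques. The canonical group-mean
network positions on the normalized gradient are available as an alternative
layout via :func:`canonical_coordinates`; the default LH-RH offsets follow
the canonical pattern (control/default/attention networks shifted toward the
heteromodal end on the left, the temporolimbic network the other way).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import HEMISPHERES, YEO17_NETWORKS, ParcelAtlas
from .connectivity import TimeSeriesMatrix

#: network -> (position on [0,1], population LH-RH offset) for the canonical
#: 17-network solution on the min-max normalized principal gradient.
CANONICAL_NETWORK_POSITIONS: dict[str, tuple[float, float]] = {
    "VisCent": (0.1948, -0.0037),
    "VisPeri": (0.1969, -0.0085),
    "SomMotA": (0.2851, 0.0105),
    "SomMotB": (0.2903, 0.0044),
    "DorsAttnB": (0.3107, 0.0304),
    "SalVentAttnA": (0.3338, 0.0256),
    "DorsAttnA": (0.3584, 0.0319),
    "TempPar": (0.5014, -0.0140),
    "SalVentAttnB": (0.4985, 0.0082),
    "ContA": (0.5276, -0.0039),
    "LimbicA": (0.5922, -0.0456),
    "ContC": (0.5941, 0.0019),
    "LimbicB": (0.6274, 0.0477),
    "DefaultC": (0.6605, -0.0130),
    "ContB": (0.6739, 0.0590),
    "DefaultB": (0.7469, 0.0293),
    "DefaultA": (0.8185, 0.0091),
}


@dataclass(frozen=True)
class PlantedCohortSpec:
    """Fully resolved description of a synthetic cohort.

    All mapping fields are keyed by network label (and hemisphere where
    relevant); use :func:`make_cohort_spec` to build one from scalars.
    """

    n_participants: int
    n_timepoints: int
    networks: tuple[str, ...]
    parcel_counts: Mapping[str, Mapping[str, int]]  # net -> {"L": k, "R": k}
    coordinate: Mapping[str, Mapping[str, float]]  # net -> {"L": g, "R": g}
    asymmetry_mean: Mapping[str, float]
    asymmetry_sd: Mapping[str, float]
    corr_length_tau: float = 0.3
    noise_sd: float = 0.5
    within_network_spread: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.corr_length_tau <= 0:
            raise ValueError("corr_length_tau must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.within_network_spread < 0:
            raise ValueError("within_network_spread must be >= 0")
        for net in self.networks:
            for hemi in HEMISPHERES:
                k = self.parcel_counts[net][hemi]
                if k < 1:
                    raise ValueError(
                        f"zero parcels requested in cell network={net!r} "
                        f"hemisphere={hemi!r}"
                    )
                g = self.coordinate[net][hemi]
                if not 0.0 <= g <= 1.0:
                    raise ValueError(
                        f"coordinate for {net}/{hemi} must lie in [0,1], got {g}"
                    )
            if self.asymmetry_sd[net] < 0:
                raise ValueError(f"asymmetry_sd for {net} must be >= 0")

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @property
    def n_parcels(self) -> int:
        return sum(
            self.parcel_counts[n][h] for n in self.networks for h in HEMISPHERES
        )


@dataclass(frozen=True)
class BehaviorSpec:
    """Planted coupling between one network's asymmetry and one score."""

    target_network: str
    effect_r: float = 0.4
    score_names: tuple[str, ...] = ("semantic", "span", "ravens", "perceptual")
    target_score: str = "semantic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.effect_r <= 1.0:
            raise ValueError("effect_r must lie in [-1, 1]")
        if self.target_score not in self.score_names:
            raise ValueError("target_score must be one of score_names")


def canonical_coordinates(
    networks: Sequence[str] = YEO17_NETWORKS,
) -> dict[str, dict[str, float]]:
    """Canonical group-mean network positions (both hemispheres equal)."""
    return {
        n: {"L": CANONICAL_NETWORK_POSITIONS[n][0],
            "R": CANONICAL_NETWORK_POSITIONS[n][0]}
        for n in networks
    }


def make_cohort_spec(
    n_participants: int,
    n_timepoints: int = 200,
    networks: Sequence[str] = YEO17_NETWORKS,
    parcels_per_network_per_hemisphere: int | Mapping[str, Mapping[str, int]] = 2,
    coordinate: Mapping[str, Mapping[str, float]] | None = None,
    asymmetry_mean: float | Mapping[str, float] | None = None,
    asymmetry_sd: float | Mapping[str, float] = 0.03,
    corr_length_tau: float = 0.3,
    noise_sd: float = 0.5,
    within_network_spread: float = 0.02,
    seed: int = 0,
) -> PlantedCohortSpec:
    """Build a :class:`PlantedCohortSpec` with sensible defaults.

    ``coordinate=None`` spreads the networks evenly along [0, 1] in the given
    order (for :data:`YEO17_NETWORKS` that is canonical principal-gradient
    order). ``asymmetry_mean=None`` uses the canonical LH-RH offsets for
    networks present in :data:`CANONICAL_NETWORK_POSITIONS` (0 otherwise);
    pass ``0`` for a fully symmetric (null) cohort.
    """
    networks = tuple(networks)
    if isinstance(parcels_per_network_per_hemisphere, int):
        counts = {
            n: {"L": parcels_per_network_per_hemisphere,
                "R": parcels_per_network_per_hemisphere}
            for n in networks
        }
    else:
        counts = {n: dict(parcels_per_network_per_hemisphere[n]) for n in networks}

    if coordinate is None:
        coordinate = {
            n: {"L": (i + 0.5) / len(networks), "R": (i + 0.5) / len(networks)}
            for i, n in enumerate(networks)
        }
    else:
        coordinate = {n: dict(coordinate[n]) for n in networks}

    if asymmetry_mean is None:
        amean = {
            n: CANONICAL_NETWORK_POSITIONS.get(n, (0.0, 0.0))[1] for n in networks
        }
    elif isinstance(asymmetry_mean, Mapping):
        amean = {n: float(asymmetry_mean.get(n, 0.0)) for n in networks}
    else:
        amean = {n: float(asymmetry_mean) for n in networks}

    if isinstance(asymmetry_sd, Mapping):
        asd = {n: float(asymmetry_sd.get(n, 0.0)) for n in networks}
    else:
        asd = {n: float(asymmetry_sd) for n in networks}

    return PlantedCohortSpec(
        n_participants=n_participants,
        n_timepoints=n_timepoints,
        networks=networks,
        parcel_counts=counts,
        coordinate=coordinate,
        asymmetry_mean=amean,
        asymmetry_sd=asd,
        corr_length_tau=corr_length_tau,
        noise_sd=noise_sd,
        within_network_spread=within_network_spread,
        seed=seed,
    )


def study_cohort_spec(
    n_participants: int = 20,
    n_timepoints: int = 200,
    noise_sd: float = 0.5,
    asymmetry_mean: float | Mapping[str, float] | None = None,
    asymmetry_sd: float | Mapping[str, float] = 0.03,
    seed: int = 0,
) -> PlantedCohortSpec:
    """The package's reference cohort: 17 networks, 80 parcels.

    34 network x hemisphere cells hold 2 parcels each, and the first 12 cells
    (network-major order) hold 3, for a fixed 80-parcel layout.
    """
    counts: dict[str, dict[str, int]] = {}
    cell = 0
    for n in YEO17_NETWORKS:
        counts[n] = {}
        for h in HEMISPHERES:
            counts[n][h] = 3 if cell < 12 else 2
            cell += 1
    return make_cohort_spec(
        n_participants=n_participants,
        n_timepoints=n_timepoints,
        parcels_per_network_per_hemisphere=counts,
        asymmetry_mean=asymmetry_mean,
        asymmetry_sd=asymmetry_sd,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# atlas / coordinates
# ---------------------------------------------------------------------------

def generate_atlas(spec: PlantedCohortSpec) -> ParcelAtlas:
    """Deterministic atlas for the cohort: network-major, L before R."""
    rows = []
    for net in spec.networks:
        for hemi in HEMISPHERES:
            for k in range(spec.parcel_counts[net][hemi]):
                rows.append(
                    {
                        "parcel_id": f"{net}_{hemi}_{k}",
                        "hemisphere": hemi,
                        "network": net,
                    }
                )
    return ParcelAtlas(pd.DataFrame(rows))


def participant_ids(spec: PlantedCohortSpec) -> list[str]:
    return [f"sub-{i:03d}" for i in range(spec.n_participants)]


def _subject_rng(spec: PlantedCohortSpec, participant_index: int) -> np.random.Generator:
    # per-subject stream keyed on (seed, index): reproducible under parallel
    # generation and independent of how many subjects were drawn before
    return np.random.default_rng([int(spec.seed), int(participant_index)])


def _draw_offsets(
    spec: PlantedCohortSpec, rng: np.random.Generator
) -> dict[str, float]:
    return {
        net: float(rng.normal(spec.asymmetry_mean[net], spec.asymmetry_sd[net]))
        for net in spec.networks
    }


def _parcel_base_coordinates(
    spec: PlantedCohortSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population parcel coordinates (with within-network spread applied),
    plus parallel network and hemisphere label arrays in atlas order."""
    g, nets, hemis = [], [], []
    for net in spec.networks:
        for hemi in HEMISPHERES:
            k = spec.parcel_counts[net][hemi]
            center = spec.coordinate[net][hemi]
            spread = (
                np.linspace(-spec.within_network_spread,
                            spec.within_network_spread, k)
                if k > 1 else np.zeros(1)
            )
            g.extend(center + spread)
            nets.extend([net] * k)
            hemis.extend([hemi] * k)
    return np.asarray(g), np.asarray(nets), np.asarray(hemis)


def subject_coordinates(
    spec: PlantedCohortSpec, participant_index: int
) -> tuple[np.ndarray, dict[str, float]]:
    """Planted parcel coordinates for one participant, plus their per-network
    LH offsets. Offsets are added to left-hemisphere parcels only."""
    if not 0 <= participant_index < spec.n_participants:
        raise IndexError("participant_index out of range")
    rng = _subject_rng(spec, participant_index)
    offsets = _draw_offsets(spec, rng)
    base, nets, hemis = _parcel_base_coordinates(spec)
    g = base + np.where(
        hemis == "L", np.array([offsets[n] for n in nets]), 0.0
    )
    return g, offsets


def subject_asymmetries(spec: PlantedCohortSpec) -> pd.DataFrame:
    """Planted per-subject LH-RH coordinate offsets (participants x networks).

    Drawn from the same per-subject streams as :func:`generate_timeseries`,
    so the returned table is the ground truth for any cohort generated from
    ``spec``.
    """
    rows = {}
    for i, pid in enumerate(participant_ids(spec)):
        rng = _subject_rng(spec, i)
        rows[pid] = _draw_offsets(spec, rng)
    out = pd.DataFrame.from_dict(rows, orient="index")[list(spec.networks)]
    out.index.name = "participant_id"
    return out


# ---------------------------------------------------------------------------
# time-series
# ---------------------------------------------------------------------------

def planted_covariance(g: np.ndarray, tau: float) -> np.ndarray:
    """Latent covariance exp(-|g_i - g_j| / tau) (unit variance)."""
    return np.exp(-np.abs(g[:, None] - g[None, :]) / tau)


def generate_timeseries(
    spec: PlantedCohortSpec, participant_index: int
) -> TimeSeriesMatrix:
    """T x P Gaussian time-series whose latent inter-parcel correlation is the
    planted exponential-decay kernel, plus independent observation noise."""
    rng = _subject_rng(spec, participant_index)
    offsets = _draw_offsets(spec, rng)
    base, nets, hemis = _parcel_base_coordinates(spec)
    g = base + np.where(
        hemis == "L", np.array([offsets[n] for n in nets]), 0.0
    )
    atlas = generate_atlas(spec)
    cov = planted_covariance(g, spec.corr_length_tau)
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError(
            "implied covariance is not positive semidefinite; "
            "increase noise_sd or corr_length_tau"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    latent = rng.standard_normal((spec.n_timepoints, len(g))) @ factor.T
    values = latent + spec.noise_sd * rng.standard_normal(latent.shape)
    return TimeSeriesMatrix(
        values=values,
        parcel_ids=atlas.parcel_ids,
        participant_id=participant_ids(spec)[participant_index],
    )


def generate_cohort(spec: PlantedCohortSpec) -> Iterable[TimeSeriesMatrix]:
    for i in range(spec.n_participants):
        yield generate_timeseries(spec, i)


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def generate_behavior(
    spec: PlantedCohortSpec,
    behavior: BehaviorSpec,
    asymmetries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-participant behavioural scores, one coupled to planted asymmetry.

    The target score is ``effect_r * z(asymmetry) + sqrt(1-r^2) * noise``; all
    other scores are independent standard normals.
    """
    if behavior.target_network not in spec.networks:
        raise ValueError(f"unknown target_network {behavior.target_network!r}")
    if asymmetries is None:
        asymmetries = subject_asymmetries(spec)
    a = asymmetries[behavior.target_network].to_numpy(dtype=float)
    n = len(a)
    rng = np.random.default_rng([int(behavior.seed), 2**20])
    sd = a.std()
    if sd == 0:
        if behavior.effect_r != 0:
            raise ValueError(
                "planted asymmetry has zero variance; cannot couple a score"
            )
        z = np.zeros(n)
    else:
        z = (a - a.mean()) / sd
    out = {}
    for name in behavior.score_names:
        if name == behavior.target_score:
            noise_scale = float(np.sqrt(max(0.0, 1.0 - behavior.effect_r**2)))
            out[name] = behavior.effect_r * z + noise_scale * rng.standard_normal(n)
        else:
            out[name] = rng.standard_normal(n)
    table = pd.DataFrame(out, index=asymmetries.index)
    table.index.name = "participant_id"
    return table.reset_index()


def generate_difference_scores(
    n_participants: int,
    networks: Sequence[str],
    offsets: Mapping[str, float] | float = 0.0,
    sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample LH-RH difference scores directly from the generator's implied
    distribution (Normal(offset, sd) per network, independent across
    participants).

    This is the distribution the planted model induces on the pipeline's
    central statistic; it is used to exercise the inference layer at scales
    where re-deriving each score through the embedding adds nothing.
    Returns a tidy table (participant_id, network, diff).
    """
    rng = np.random.default_rng([int(seed), 2**21])
    if not isinstance(offsets, Mapping):
        offsets = {net: float(offsets) for net in networks}
    pids = [f"sub-{i:03d}" for i in range(n_participants)]
    rows = []
    for net in networks:
        vals = rng.normal(offsets.get(net, 0.0), sd, size=n_participants)
        rows.append(
            pd.DataFrame(
                {"participant_id": pids, "network": net, "diff": vals}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    spec: PlantedCohortSpec,
    out_dir: str | Path,
    behavior: BehaviorSpec | None = None,
) -> Path:
    """Write the cohort as delimited text: one ``sub-*_ts.tsv`` per
    participant, ``atlas.tsv``, optional ``behavior.tsv``, and ``truth.json``
    with every planted parameter needed for recovery tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = generate_atlas(spec)
    atlas.to_tsv(out / "atlas.tsv")

    for i, ts in enumerate(generate_cohort(spec)):
        df = pd.DataFrame(ts.values, columns=ts.parcel_ids)
        df.to_csv(out / f"{ts.participant_id}_ts.tsv", sep="\t", index=False)

    asym = subject_asymmetries(spec)
    truth = {
        "networks": list(spec.networks),
        "coordinate": {n: dict(spec.coordinate[n]) for n in spec.networks},
        "asymmetry_mean": dict(spec.asymmetry_mean),
        "asymmetry_sd": dict(spec.asymmetry_sd),
        "corr_length_tau": spec.corr_length_tau,
        "noise_sd": spec.noise_sd,
        "within_network_spread": spec.within_network_spread,
        "parcel_coordinates": {
            pid_: float(gv)
            for pid_, gv in zip(atlas.parcel_ids, _parcel_base_coordinates(spec)[0])
        },
        "seed": spec.seed,
        "n_timepoints": spec.n_timepoints,
        "subject_asymmetries": {
            pid: {n: float(v) for n, v in row.items()}
            for pid, row in asym.iterrows()
        },
    }
    if behavior is not None:
        generate_behavior(spec, behavior, asym).to_csv(
            out / "behavior.tsv", sep="\t", index=False
        )
        truth["behavior"] = {
            "target_network": behavior.target_network,
            "effect_r": behavior.effect_r,
            "target_score": behavior.target_score,
        }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return out
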