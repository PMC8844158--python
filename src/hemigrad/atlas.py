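"""Parcel atlas: maps each cortical parcel to a hemisphere and a functional network.

Emulates the structure of a Schaefer-style parcellation grouped into the 17
canonical resting-state (Yeo) networks. Hemispheres may contribute unequal
parcel counts to a network; nothing downstream assumes homotopic parcels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

HEMISPHERES = ("L", "R")

#: Canonical 17-network labels (Yeo et al. 17-network solution), ordered
#: roughly from the unimodal to the heteromodal end of the principal gradient.
YEO17_NETWORKS = (
    "VisCent",
    "VisPeri",
    "SomMotA",
    "SomMotB",
    "DorsAttnB",
    "SalVentAttnA",
    "DorsAttnA",
    "TempPar",
    "SalVentAttnB",
    "ContA",
    "LimbicA",
    "ContC",
    "LimbicB",
    "DefaultC",
    "ContB",
    "DefaultB",
    "DefaultA",
)


@dataclass(frozen=True)
class ParcelAtlas:
    """Lookup table with one row per parcel: parcel_id, hemisphere, network."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"parcel_id", "hemisphere", "network"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        if self.table["parcel_id"].duplicated().any():
            dupes = self.table.loc[self.table["parcel_id"].duplicated(), "parcel_id"]
            raise ValueError(f"duplicate parcel ids: {list(dupes)[:5]}")
        bad = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"hemisphere labels must be L/R, got {sorted(bad)}")

    @property
    def parcel_ids(self) -> list[str]:
        return list(self.table["parcel_id"])

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Network labels in order of first appearance."""
        return list(dict.fromkeys(self.table["network"]))

    def parcels_in(self, network: str, hemisphere: str | None = None) -> list[str]:
        mask = self.table["network"] == network
        if hemisphere is not None:
            mask &= self.table["hemisphere"] == hemisphere
        return list(self.table.loc[mask, "parcel_id"])

    def counts(self) -> pd.DataFrame:
        """Parcel counts per network x hemisphere (zero-filled)."""
        return (
            self.table.groupby(["network", "hemisphere"], sort=False)
            .size()
            .unstack(fill_value=0)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcelAtlas":
        return cls(pd.read_csv(path, sep="\t", dtype={"parcel_id": str}))
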