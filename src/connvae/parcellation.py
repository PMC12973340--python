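"""Parcellation scheme: parcels, hemispheres, and hemisphere-specific networks.

The reference scheme unifies 200 Schaefer cortical parcels (100 per hemisphere,
labelled with the 17 Yeo networks) with 10 AAL3 subcortical regions (thalamus,
caudate, putamen, pallidum, hippocampus, left and right).  For network-level
statistics the subcortical regions of each hemisphere are merged into a single
"Subcortical" network, giving 18 networks per hemisphere, 36 in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")

#: Yeo 17-network labels used by the Schaefer cortical parcellation.
YEO17_NETWORKS = (
    "VisCent", "VisPeri", "SomMotA", "SomMotB", "DorsAttnA", "DorsAttnB",
    "SalVentAttnA", "SalVentAttnB", "LimbicA", "LimbicB", "ControlA",
    "ControlB", "ControlC", "DefaultA", "DefaultB", "DefaultC", "TempPar",
)

#: AAL3 subcortical region labels merged into one network per hemisphere.
SUBCORTICAL_REGIONS = ("Thalamus", "Caudate", "Putamen", "Pallidum", "Hippocampus")

SUBCORTICAL_LABEL = "Subcortical"


class ParcellationError(ValueError):
    """Raised when a parcellation table violates the scheme contract."""


@dataclass(frozen=True)
class ParcellationScheme:
    """Immutable parcel -> (hemisphere, network) mapping.

    ``network`` holds the merged labels (subcortical regions collapsed into
    :data:`SUBCORTICAL_LABEL`); ``raw_network`` keeps the labels as read.
    ``network_index`` maps each parcel to an index into ``networks``, the
    ordered list of distinct (hemisphere, network) pairs.
    """

    parcel_ids: tuple[str, ...]
    hemisphere: tuple[str, ...]
    raw_network: tuple[str, ...]
    network: tuple[str, ...] = field(init=False)
    networks: tuple[tuple[str, str], ...] = field(init=False)
    network_index: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ParcellationError("duplicate parcel ids")
        if not self.parcel_ids:
            raise ParcellationError("empty parcellation")
        bad = set(self.hemisphere) - set(HEMISPHERES)
        if bad:
            raise ParcellationError(f"unknown hemisphere label(s): {sorted(bad)}")
        if not (len(self.parcel_ids) == len(self.hemisphere) == len(self.raw_network)):
            raise ParcellationError("column length mismatch")
        merged = tuple(
            SUBCORTICAL_LABEL if n in SUBCORTICAL_REGIONS else n
            for n in self.raw_network
        )
        object.__setattr__(self, "network", merged)
        pairs: list[tuple[str, str]] = []
        for h, n in zip(self.hemisphere, merged):
            if (h, n) not in pairs:
                pairs.append((h, n))
        object.__setattr__(self, "networks", tuple(pairs))
        index = np.array([pairs.index((h, n)) for h, n in zip(self.hemisphere, merged)])
        object.__setattr__(self, "network_index", index)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    def networks_in_hemisphere(self, hemisphere: str) -> list[tuple[str, str]]:
        return [p for p in self.networks if p[0] == hemisphere]

    def parcels_in_network(self, network_idx: int) -> np.ndarray:
        """Indices of the parcels belonging to network ``network_idx``."""
        return np.flatnonzero(self.network_index == network_idx)

    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.network_index, minlength=self.n_networks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "hemisphere": self.hemisphere,
                "network": self.raw_network,
            }
        )


def scheme_from_frame(df: pd.DataFrame) -> ParcellationScheme:
    required = {"parcel_id", "hemisphere", "network"}
    missing = required - set(df.columns)
    if missing:
        raise ParcellationError(f"parcellation table missing columns: {sorted(missing)}")
    return ParcellationScheme(
        parcel_ids=tuple(str(p) for p in df["parcel_id"]),
        hemisphere=tuple(str(h) for h in df["hemisphere"]),
        raw_network=tuple(str(n) for n in df["network"]),
    )


def read_parcellation(path) -> ParcellationScheme:
    """Read a tab-separated parcellation table (parcel_id, hemisphere, network)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return scheme_from_frame(df)


def write_parcellation(scheme: ParcellationScheme, path) -> None:
    scheme.to_frame().to_csv(path, sep="\t", index=False)


def _schaefer_network_sizes() -> list[int]:
    # 100 cortical parcels per hemisphere over 17 networks: 15 networks of 6
    # parcels and 2 of 5, fixed ordering.
    sizes = [6] * len(YEO17_NETWORKS)
    sizes[-1] = 5
    sizes[-2] = 5
    return sizes


def default_scheme() -> ParcellationScheme:
    """The 210-parcel reference scheme (2 x 100 cortical + 2 x 5 subcortical)."""
    ids, hemis, nets = [], [], []
    for hemi, tag in (("left", "LH"), ("right", "RH")):
        for net, size in zip(YEO17_NETWORKS, _schaefer_network_sizes()):
            for k in range(size):
                ids.append(f"{tag}_{net}_{k + 1}")
                hemis.append(hemi)
                nets.append(net)
        for region in SUBCORTICAL_REGIONS:
            ids.append(f"{tag}_{region}")
            hemis.append(hemi)
            nets.append(region)
    return ParcellationScheme(tuple(ids), tuple(hemis), tuple(nets))


def synthetic_scheme(n_parcels: int, networks_per_hemisphere: int) -> ParcellationScheme:
    """A reduced scheme for simulation: ``n_parcels`` split evenly over two
    hemispheres and ``networks_per_hemisphere`` generic networks each."""
    if n_parcels % 2:
        raise ParcellationError("n_parcels must be even (two hemispheres)")
    per_hemi = n_parcels // 2
    if networks_per_hemisphere < 1 or networks_per_hemisphere > per_hemi:
        raise ParcellationError("invalid networks_per_hemisphere")
    ids, hemis, nets = [], [], []
    for hemi, tag in (("left", "LH"), ("right", "RH")):
        for i in range(per_hemi):
            net = i * networks_per_hemisphere // per_hemi
            ids.append(f"{tag}_Net{net + 1:02d}_{i + 1}")
            hemis.append(hemi)
            nets.append(f"Net{net + 1:02d}")
    return ParcellationScheme(tuple(ids), tuple(hemis), tuple(nets))
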