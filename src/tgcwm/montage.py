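"""Standard 64-channel 10-10 montage and the scalp-region electrode map.

The region map groups 46 of the 64 electrodes into eight scalp regions
(left/right frontal, central, temporal, occipital) used for all regional
band-power and coupling aggregation. Midline electrodes and the mastoid-
adjacent FT9/FT10/TP9/TP10 sites belong to no region.
"""

from __future__ import annotations

# Brain Products / Neuracle style 64-channel 10-10 layout.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

DEFAULT_REGIONS: dict[str, tuple[str, ...]] = {
    "left_frontal": ("Fp1", "AF3", "AF7", "F1", "F3", "F5", "F7", "FC1", "FC3", "FC5"),
    "right_frontal": ("Fp2", "AF4", "AF8", "F2", "F4", "F6", "F8", "FC2", "FC4", "FC6"),
    "left_central": ("C1", "C3", "C5", "CP1", "CP3", "CP5"),
    "right_central": ("C2", "C4", "C6", "CP2", "CP4", "CP6"),
    "left_temporal": ("FT7", "T7", "TP7"),
    "right_temporal": ("FT8", "T8", "TP8"),
    "left_occipital": ("P3", "P5", "P7", "PO3", "PO7", "O1"),
    "right_occipital": ("P4", "P6", "P8", "PO4", "PO8", "O2"),
}


class RegionMap:
    """Mapping from scalp-region name to electrode labels.

    Invariants enforced on construction: no electrode belongs to two
    regions, and every electrode resolves in the supplied montage.
    """

    def __init__(
        self,
        regions: dict[str, tuple[str, ...]] | None = None,
        montage: tuple[str, ...] | list[str] = CHANNELS_64,
    ) -> None:
        regions = dict(regions if regions is not None else DEFAULT_REGIONS)
        seen: dict[str, str] = {}
        montage_set = set(montage)
        for region, electrodes in regions.items():
            for el in electrodes:
                if el in seen:
                    raise ValueError(
                        f"electrode {el!r} assigned to both {seen[el]!r} and {region!r}"
                    )
                if el not in montage_set:
                    raise ValueError(
                        f"region {region!r} electrode {el!r} not in montage"
                    )
                seen[el] = region
        self.regions = {k: tuple(v) for k, v in regions.items()}

    def __getitem__(self, region: str) -> tuple[str, ...]:
        return self.regions[region]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def items(self):
        return self.regions.items()

    def electrodes(self) -> list[str]:
        """All mapped electrodes, in region order."""
        return [el for els in self.regions.values() for el in els]
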