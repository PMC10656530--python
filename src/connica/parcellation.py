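"""Parcellation lookup tables (Schaefer-style cortical atlas plus subcortex).

A parcellation assigns every ROI a name, a hemisphere and a resting-state
network label.  The pipeline only needs the label level: no coordinates or
voxel masks are handled here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven cortical resting-state networks plus the subcortical block.
CORTICAL_NETWORKS = ("VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN")
SUBCORTICAL = "subcortical"

#: FreeSurfer-style bilateral subcortical structures (8 per hemisphere).
_SUBCORTICAL_NAMES = (
    "Thalamus",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens",
    "VentralDC",
)


@dataclass(frozen=True)
class ParcellationScheme:
    """ROI lookup table: id (1-based, contiguous), name, hemisphere, network."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"roi_id", "roi_name", "hemisphere", "network"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"parcellation table missing columns: {sorted(missing)}")
        ids = self.table["roi_id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("roi_id must be unique and contiguous from 1")
        if self.table["network"].isna().any():
            raise ValueError("every ROI needs a network label")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        r = self.n_rois
        return r * (r - 1) // 2

    @property
    def networks(self) -> list[str]:
        """Network labels in first-appearance order."""
        return list(dict.fromkeys(self.table["network"]))

    def network_of(self) -> np.ndarray:
        """Per-ROI network label, index 0 .. R-1 for roi_id 1 .. R."""
        return self.table["network"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcellationScheme":
        return cls(pd.read_csv(path, sep="\t"))


def make_parcellation(n_rois: int = 100, n_subcortical: int = 16) -> ParcellationScheme:
    """Build a Schaefer-like lookup table with ``n_rois`` regions.

    Cortical ROIs (``n_rois - n_subcortical``) are split evenly between
    hemispheres and assigned to the seven canonical networks in contiguous
    runs per hemisphere, mirroring how atlas lookup tables order parcels.
    The last ``n_subcortical`` ROIs are bilateral subcortical structures.
    The full-scale table is ``make_parcellation(408)``: 400 cortical parcels
    plus 8 bilateral (16) subcortical regions.
    """
    if n_subcortical % 2:
        raise ValueError("n_subcortical must be even (bilateral structures)")
    n_cortical = n_rois - n_subcortical
    if n_cortical < 2 * len(CORTICAL_NETWORKS):
        raise ValueError(
            f"need at least {2 * len(CORTICAL_NETWORKS) + n_subcortical} ROIs "
            "for one parcel per network per hemisphere"
        )
    rows = []
    per_hemi = n_cortical // 2
    extra_left = n_cortical - 2 * per_hemi
    for hemi, count in (("L", per_hemi + extra_left), ("R", per_hemi)):
        # contiguous runs of parcels per network, like the Schaefer LUT
        bounds = np.linspace(0, count, len(CORTICAL_NETWORKS) + 1).astype(int)
        for k, net in enumerate(CORTICAL_NETWORKS):
            for i in range(bounds[k], bounds[k + 1]):
                rows.append((f"{hemi}_{net}_{i - bounds[k] + 1}", hemi, net))
    half = n_subcortical // 2
    for hemi in ("L", "R"):
        for i in range(half):
            name = _SUBCORTICAL_NAMES[i % len(_SUBCORTICAL_NAMES)]
            suffix = "" if i < len(_SUBCORTICAL_NAMES) else f"_{i // len(_SUBCORTICAL_NAMES) + 1}"
            rows.append((f"{hemi}_{name}{suffix}", hemi, SUBCORTICAL))
    table = pd.DataFrame(rows, columns=["roi_name", "hemisphere", "network"])
    table.insert(0, "roi_id", np.arange(1, len(table) + 1))
    return ParcellationScheme(table)
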