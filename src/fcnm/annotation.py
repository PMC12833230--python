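"""Canonical-network composition of a consensus network.

Decomposes an :class:`~fcnm.fcnm_core.AcupointNetwork` into the seven
canonical cortical systems (visual, somatomotor, dorsal attention, ventral
attention, limbic, frontoparietal control, default) plus one aggregate
subcortical category, by overlap proportion: for each canonical label L,
``|network ∩ L| / |network|``.  The denominator is always the network size,
so proportions (including the unassigned background fraction) sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcnm_core import AcupointNetwork
from .grid_io import ReferenceGrid

__all__ = [
    "CANONICAL_NAMES",
    "SUBCORTICAL_STRUCTURES",
    "CanonicalAtlas",
    "OverlapProfile",
    "EmptyNetworkError",
    "overlap_profile",
    "profile_report",
]

CANONICAL_NAMES = (
    "visual",
    "somatomotor",
    "dorsal attention",
    "ventral attention",
    "limbic",
    "frontoparietal control",
    "default",
    "subcortical",
)

#: structures merged into the aggregate "subcortical" category
SUBCORTICAL_STRUCTURES = (
    "thalamus",
    "caudate",
    "putamen",
    "pallidum",
    "hippocampus",
    "amygdala",
    "nucleus accumbens",
)


class EmptyNetworkError(ValueError):
    """Overlap profile of an empty network is undefined."""


@dataclass
class CanonicalAtlas:
    """Hard integer-label parcellation into canonical systems (0 = background).

    ``label_names`` maps each nonzero integer to one of
    :data:`CANONICAL_NAMES` or to a subcortical structure name (those are
    merged into "subcortical" when profiling, with a per-structure
    breakdown retained).
    """

    grid: ReferenceGrid
    labels: np.ndarray
    label_names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("atlas label volume shape mismatch")
        for lab, name in self.label_names.items():
            if lab == 0:
                raise ValueError("0 is reserved for background")
            if name not in CANONICAL_NAMES and name not in SUBCORTICAL_STRUCTURES:
                raise ValueError(f"unknown canonical name {name!r}")
            if not (self.labels == lab).any():
                raise ValueError(f"label {lab} ({name}) occurs in no voxel")

    def canonical_name(self, label: int) -> str:
        name = self.label_names[label]
        return "subcortical" if name in SUBCORTICAL_STRUCTURES else name


@dataclass
class OverlapProfile:
    """Per-canonical-network overlap proportions of one consensus network."""

    proportions: dict[str, float]
    network_size_voxels: int
    unassigned: float
    subcortical_breakdown: dict[str, float] | None = None

    def __post_init__(self):
        total = sum(self.proportions.values()) + self.unassigned
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


def overlap_profile(network: AcupointNetwork, atlas: CanonicalAtlas) -> OverlapProfile:
    """Proportion of network voxels falling in each canonical system."""
    network.grid.require_match(atlas.grid)
    size = network.n_voxels
    if size == 0:
        raise EmptyNetworkError(
            f"network {network.acupoint!r} is empty; profile undefined"
        )
    labels_in = atlas.labels[network.mask]
    props = {name: 0.0 for name in CANONICAL_NAMES}
    breakdown = {name: 0.0 for name in SUBCORTICAL_STRUCTURES}
    unassigned = 0.0
    vals, counts = np.unique(labels_in, return_counts=True)
    for lab, count in zip(vals, counts):
        frac = count / size
        if lab == 0:
            unassigned += frac
        elif int(lab) in atlas.label_names:
            raw = atlas.label_names[int(lab)]
            props[atlas.canonical_name(int(lab))] += frac
            if raw in SUBCORTICAL_STRUCTURES:
                breakdown[raw] += frac
        else:
            unassigned += frac  # unnamed label treated as background
    return OverlapProfile(
        proportions=props,
        network_size_voxels=size,
        unassigned=float(unassigned),
        subcortical_breakdown=breakdown,
    )


def profile_report(profiles: dict[str, OverlapProfile]) -> pd.DataFrame:
    """Long-format ranked table of overlap proportions across acupoints.

    Within each acupoint, rows are sorted by descending proportion; ties
    break on label name so the order is stable.  Suitable for CSV export
    and polar plots.
    """
    rows = []
    for acupoint in sorted(profiles):
        prof = profiles[acupoint]
        items = sorted(prof.proportions.items(), key=lambda kv: (-kv[1], kv[0]))
        for rank, (name, prop) in enumerate(items, start=1):
            rows.append(
                {
                    "acupoint": acupoint,
                    "rank": rank,
                    "canonical_network": name,
                    "proportion": prop,
                    "network_size_voxels": prof.network_size_voxels,
                    "unassigned": prof.unassigned,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "acupoint", "rank", "canonical_network",
            "proportion", "network_size_voxels", "unassigned",
        ],
    )
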