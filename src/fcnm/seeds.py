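"""Spherical seed masks around reported activation coordinates.

Each included study (or contrast) contributes a *contrast seed*: the union
of small spheres (default radius 4 mm) around every coordinate it reports.
Sphere membership is by voxel-center distance, so a 1 mm sphere on a 3 mm
grid still yields the single containing voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid_io import (
    CoordinateOutOfGridError,
    FocusRecord,
    ReferenceGrid,
    mm_to_voxel,
    voxel_to_mm,
)

__all__ = ["SeedSpec", "SeedMask", "EmptySeedError", "build_seed", "seeds_per_unit"]

log = logging.getLogger(__name__)


class EmptySeedError(ValueError):
    """All of a unit's seed voxels fell outside the brain mask."""


@dataclass(frozen=True)
class SeedSpec:
    """Seed geometry: sphere radius in mm plus the containing-voxel rule."""

    radius_mm: float = 4.0
    always_include_containing_voxel: bool = True

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass
class SeedMask:
    """Voxel set forming one contrast seed on the session grid."""

    grid: ReferenceGrid
    voxels: frozenset[tuple[int, int, int]]
    source_contrast: str = ""

    def __post_init__(self):
        if not self.voxels:
            raise EmptySeedError(f"empty seed mask for {self.source_contrast!r}")
        shape = np.array(self.grid.shape)
        for v in self.voxels:
            if (np.array(v) < 0).any() or (np.array(v) >= shape).any():
                raise ValueError(f"seed voxel {v} outside grid bounds")

    def as_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=bool)
        idx = np.array(sorted(self.voxels))
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return vol

    def __len__(self) -> int:
        return len(self.voxels)


def _sphere_voxels(grid: ReferenceGrid, center_mm: np.ndarray, radius_mm: float):
    """Voxels whose centers lie within radius_mm of center_mm (Euclidean)."""
    # search box in voxel space around the coordinate
    inv = np.linalg.inv(grid.affine)
    center_vox = (inv @ np.append(center_mm, 1.0))[:3]
    half_extent = radius_mm / grid.voxel_size_mm + 1.0
    lo = np.maximum(np.floor(center_vox - half_extent).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half_extent).astype(int) + 1,
                    np.array(grid.shape))
    if (lo >= hi).any():
        return set()
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = vox @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    dist = np.linalg.norm(centers - center_mm, axis=1)
    keep = vox[dist <= radius_mm + 1e-9]
    return {tuple(int(x) for x in v) for v in keep}


def build_seed(
    foci: list[FocusRecord],
    spec: SeedSpec,
    grid: ReferenceGrid,
    source_contrast: str = "",
) -> SeedMask:
    """Union-of-spheres seed mask for a set of MNI-space foci.

    Voxels outside the brain mask are dropped with a warning; if every voxel
    of the union falls outside, :class:`EmptySeedError` is raised naming the
    contrast.
    """
    if not foci:
        raise ValueError("no foci given")
    voxels: set[tuple[int, int, int]] = set()
    for focus in foci:
        if focus.space != "MNI":
            raise ValueError(
                f"focus from {focus.study_id} is in {focus.space}; convert to MNI first"
            )
        sphere = _sphere_voxels(grid, focus.coord_mm, spec.radius_mm)
        if spec.always_include_containing_voxel:
            try:
                sphere.add(mm_to_voxel(grid, focus.coord_mm))
            except CoordinateOutOfGridError:
                log.warning(
                    "focus %s (%.1f, %.1f, %.1f) falls outside the grid",
                    focus.study_id, focus.x, focus.y, focus.z,
                )
        kept = {v for v in sphere if grid.brain_mask[v]}
        if sphere and not kept:
            log.warning(
                "focus %s (%.1f, %.1f, %.1f): whole sphere outside brain mask",
                focus.study_id, focus.x, focus.y, focus.z,
            )
        voxels |= kept
    if not voxels:
        raise EmptySeedError(
            f"seed for contrast {source_contrast!r} is empty after brain masking"
        )
    return SeedMask(grid, frozenset(voxels), source_contrast=source_contrast)


def seeds_per_unit(
    records: list[FocusRecord],
    unit: str,
    spec: SeedSpec,
    grid: ReferenceGrid,
) -> dict[str, SeedMask]:
    """One seed mask per aggregation unit.

    ``unit='study'`` pools all contrasts of a study into one seed (default
    for probability maps with per-study counts); ``unit='contrast'`` keeps
    one seed per (study, contrast) pair.
    """
    if unit not in ("study", "contrast"):
        raise ValueError(f"unit must be 'study' or 'contrast', got {unit!r}")
    groups: dict[str, list[FocusRecord]] = {}
    for rec in records:
        key = rec.study_id if unit == "study" else f"{rec.study_id}:{rec.contrast_id}"
        groups.setdefault(key, []).append(rec)
    return {
        key: build_seed(foci, spec, grid, source_contrast=key)
        for key, foci in groups.items()
    }
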