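"""Reference grid handling, NIfTI and foci-table I/O, coordinate conversions.

All volumes in a session live on a single :class:`ReferenceGrid` (shape +
affine + brain mask).  Coordinates are RAS millimetres; voxel indices are
0-based.  Inputs whose affine disagrees with the session grid raise
:class:`GridMismatchError` rather than being silently resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ReferenceGrid",
    "FocusRecord",
    "VolumeSeries",
    "ScalarMap",
    "GridMismatchError",
    "CoordinateOutOfGridError",
    "FociValidationError",
    "mni152_3mm_grid",
    "mm_to_voxel",
    "voxel_to_mm",
    "tal2mni",
    "read_foci_table",
    "read_volume",
    "write_volume",
]

MIN_SUBJECTS = 10  # studies with fewer participants are excluded

SPACE_ALIASES = {
    "mni": "MNI",
    "mni152": "MNI",
    "icbm": "MNI",
    "tal": "Talairach",
    "talairach": "Talairach",
    "tlrc": "Talairach",
}

#: Lancaster et al. "icbm_spm2tal" affine, mapping MNI (SPM) mm -> Talairach mm.
#: tal2mni applies its inverse.
ICBM_SPM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

_TAL2MNI_LANCASTER = np.linalg.inv(ICBM_SPM2TAL)

#: Brett "mni2tal" transforms (separate matrices above/below the AC plane).
_BRETT_UP = np.array(
    [
        [0.99, 0.0, 0.0, 0.0],
        [0.0, 0.9688, 0.046, 0.0],
        [0.0, -0.0485, 0.9189, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_BRETT_DOWN = np.array(
    [
        [0.99, 0.0, 0.0, 0.0],
        [0.0, 0.9688, 0.042, 0.0],
        [0.0, -0.0485, 0.839, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


class GridMismatchError(ValueError):
    """A volume's shape or affine disagrees with the session ReferenceGrid."""


class CoordinateOutOfGridError(ValueError):
    """A mm coordinate maps outside the grid bounds."""


class FociValidationError(ValueError):
    """One or more foci-table rows violate the input contract."""


@dataclass(frozen=True)
class ReferenceGrid:
    """Common sampling grid: shape, voxel->mm affine, and brain mask."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != tuple(self.shape):
            raise ValueError(
                f"brain_mask shape {mask.shape} != grid shape {tuple(self.shape)}"
            )
        if not mask.any():
            raise ValueError("brain_mask has no true voxel")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "brain_mask", mask)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def matches(self, other: "ReferenceGrid", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "ReferenceGrid") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"grid mismatch: shape {other.shape} / affine differs from "
                f"session grid {self.shape}"
            )


@dataclass(frozen=True)
class FocusRecord:
    """One reported activation coordinate with study/contrast metadata."""

    study_id: str
    contrast_id: str
    acupoint: str
    x: float
    y: float
    z: float
    space: str
    n_subjects: int

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinate in {self.study_id}")
        if self.space not in ("MNI", "Talairach"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.n_subjects < MIN_SUBJECTS:
            raise ValueError(
                f"study {self.study_id}: sample size {self.n_subjects} < {MIN_SUBJECTS}"
            )

    @property
    def coord_mm(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def to_mni(self, method: str = "lancaster") -> "FocusRecord":
        """Return an MNI-space copy (Talairach coordinates converted)."""
        if self.space == "MNI":
            return self
        x, y, z = tal2mni((self.x, self.y, self.z), method=method)
        return FocusRecord(
            self.study_id, self.contrast_id, self.acupoint,
            float(x), float(y), float(z), "MNI", self.n_subjects,
        )


@dataclass
class VolumeSeries:
    """A 4D resting-state volume (3 spatial axes x T timepoints) on a grid."""

    grid: ReferenceGrid
    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries data must be 4D")
        if self.data.shape[:3] != self.grid.shape:
            raise GridMismatchError(
                f"series spatial shape {self.data.shape[:3]} != grid {self.grid.shape}"
            )
        if self.data.shape[3] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.isfinite(self.data[self.grid.brain_mask]).all():
            raise ValueError("non-finite values inside brain mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class ScalarMap:
    """A 3D scalar volume tagged with what it holds (t, p, z, probability...)."""

    grid: ReferenceGrid
    data: np.ndarray
    kind: str = "z"

    KINDS = ("t", "p", "z", "probability", "density", "gm", "label", "binary")

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape:
            raise GridMismatchError(
                f"map shape {self.data.shape} != grid {self.grid.shape}"
            )
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.kind == "probability":
            inmask = self.data[self.grid.brain_mask]
            if inmask.size and (inmask.min() < -1e-9 or inmask.max() > 1 + 1e-9):
                raise ValueError("probability map values outside [0, 1]")


def mni152_3mm_grid(mask: np.ndarray | None = None) -> ReferenceGrid:
    """Standard 61x73x61 MNI152 grid at 3 mm (SPM convention, LAS-stored affine)."""
    shape = (61, 73, 61)
    affine = np.array(
        [
            [-3.0, 0.0, 0.0, 90.0],
            [0.0, 3.0, 0.0, -126.0],
            [0.0, 0.0, 3.0, -72.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return ReferenceGrid(shape, affine, mask)


def _round_half_away(values: np.ndarray) -> np.ndarray:
    # np.round uses banker's rounding; seed membership must not depend on that
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def mm_to_voxel(grid: ReferenceGrid, coord_mm: Sequence[float]) -> tuple[int, int, int]:
    """Nearest voxel index for a mm coordinate (round half away from zero)."""
    coord = np.asarray(coord_mm, dtype=float)
    homog = np.append(coord, 1.0)
    idx_f = (np.linalg.inv(grid.affine) @ homog)[:3]
    idx = _round_half_away(idx_f).astype(int)
    if (idx < 0).any() or (idx >= np.array(grid.shape)).any():
        raise CoordinateOutOfGridError(
            f"mm coordinate {tuple(coord)} maps to voxel {tuple(idx)} outside "
            f"grid of shape {grid.shape}"
        )
    return tuple(int(i) for i in idx)


def voxel_to_mm(grid: ReferenceGrid, voxel: Sequence[int]) -> np.ndarray:
    """mm coordinate of a voxel center."""
    homog = np.append(np.asarray(voxel, dtype=float), 1.0)
    return (grid.affine @ homog)[:3]


def tal2mni(coord_tal: Sequence[float], method: str = "lancaster") -> np.ndarray:
    """Convert a Talairach mm coordinate to MNI mm.

    ``method='lancaster'`` (default) applies the inverse of the Lancaster
    icbm_spm2tal affine; ``method='brett'`` inverts the Brett mni2tal
    piecewise transform (matrix chosen by the sign of the *output* z, i.e.
    the input is mapped with whichever inverse is self-consistent).
    """
    coord = np.append(np.asarray(coord_tal, dtype=float), 1.0)
    if method == "lancaster":
        return (_TAL2MNI_LANCASTER @ coord)[:3]
    if method == "brett":
        up = (np.linalg.inv(_BRETT_UP) @ coord)[:3]
        down = (np.linalg.inv(_BRETT_DOWN) @ coord)[:3]
        # Brett's forward split is on MNI z >= 0; pick the consistent branch
        return up if up[2] >= 0 else down
    raise ValueError(f"unknown Talairach conversion method {method!r}")


REQUIRED_FOCI_COLUMNS = (
    "study_id", "contrast_id", "acupoint", "x", "y", "z", "space", "n_subjects",
)


def read_foci_table(path: str | Path) -> list[FocusRecord]:
    """Read a foci CSV/TSV into validated :class:`FocusRecord` rows.

    Row order is preserved.  Talairach rows are kept in Talairach space
    (conversion is applied downstream via :meth:`FocusRecord.to_mni`).
    Raises :class:`FociValidationError` listing every offending row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_FOCI_COLUMNS if c not in df.columns]
    if missing:
        raise FociValidationError(f"missing columns: {', '.join(missing)}")

    records: list[FocusRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header
        try:
            space = SPACE_ALIASES.get(str(row["space"]).strip().lower())
            if space is None:
                raise ValueError(f"unknown space {row['space']!r}")
            records.append(
                FocusRecord(
                    study_id=str(row["study_id"]),
                    contrast_id=str(row["contrast_id"]),
                    acupoint=str(row["acupoint"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    z=float(row["z"]),
                    space=space,
                    n_subjects=int(row["n_subjects"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise FociValidationError("; ".join(problems))
    return records


def write_foci_table(records: Iterable[FocusRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame([vars(r) for r in records], columns=REQUIRED_FOCI_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def read_volume(
    path: str | Path,
    grid: ReferenceGrid | None = None,
    kind: str = "z",
    subject_id: str = "",
):
    """Read a NIfTI file into a :class:`ScalarMap` (3D) or :class:`VolumeSeries` (4D).

    If ``grid`` is given, the file's shape/affine must match it; otherwise a
    full-mask grid is built from the header.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    affine = img.affine
    spatial = data.shape[:3]
    if grid is not None:
        file_grid = ReferenceGrid(spatial, affine, np.ones(spatial, dtype=bool))
        grid.require_match(file_grid)
        use_grid = grid
    else:
        use_grid = ReferenceGrid(spatial, affine, np.ones(spatial, dtype=bool))
    if data.ndim == 4:
        return VolumeSeries(use_grid, data, subject_id=subject_id or Path(path).stem)
    if data.ndim == 3:
        return ScalarMap(use_grid, data, kind=kind)
    raise ValueError(f"expected 3D or 4D NIfTI, got {data.ndim}D")


def write_volume(obj, path: str | Path) -> None:
    """Write a ScalarMap/VolumeSeries (or raw array + grid tuple) as NIfTI-1."""
    if isinstance(obj, (ScalarMap, VolumeSeries)):
        data, affine = obj.data, obj.grid.affine
    else:
        data, grid = obj
        affine = grid.affine
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    nib.save(img, str(path))
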