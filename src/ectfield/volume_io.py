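"""NIfTI volume I/O and assembly of masked per-subject field stacks.

All volumes in one analysis must live on a single common grid (shape +
affine): subjects are assumed to be spatially normalized to an MNI-like
space already.  Data are stored *masked* — an ``n_subjects × n_voxels``
matrix over the analysis mask — so that permutation loops only ever touch
brain voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Grid",
    "GridMismatchError",
    "StatMap",
    "SubjectFieldStack",
    "read_volume",
    "read_mask",
    "build_stack",
    "stack_from_volumes",
    "write_volume",
    "write_stat_map",
]

AFFINE_ATOL = 1e-6


class GridMismatchError(ValueError):
    """Volumes do not share the analysis grid (not co-registered)."""


@dataclass(frozen=True)
class Grid:
    """A common-space voxel grid: shape plus 4x4 voxel-to-world affine (mm)."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if abs(np.linalg.det(aff[:3, :3])) <= 0:
            raise ValueError("affine is singular")
        aff.flags.writeable = False
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3, |det| of the upper-left 3x3 block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def matches(self, other: "Grid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol, rtol=0.0
        )

    def require_match(self, other: "Grid", what: str = "volume") -> None:
        if not self.matches(other):
            raise GridMismatchError(
                f"{what} is not on the analysis grid "
                f"(shape {other.shape} vs {self.shape}, or affines differ by "
                f"more than {AFFINE_ATOL} mm): inputs must be co-registered."
            )


@dataclass
class StatMap:
    """A per-voxel statistic on the common grid, stored over a mask.

    ``values[c]`` is the statistic at masked voxel column ``c``; columns are
    ordered by (i, j, k) lexicographic voxel index.
    """

    grid: Grid
    mask: np.ndarray  # boolean volume, grid.shape
    values: np.ndarray  # 1D, one entry per True mask voxel
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if self.values.shape != (int(self.mask.sum()),):
            raise ValueError("values length does not match mask voxel count")

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[self.mask] = self.values
        return vol

    @classmethod
    def from_volume(cls, volume: np.ndarray, grid: Grid, mask: np.ndarray, name: str = "") -> "StatMap":
        volume = np.asarray(volume, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        return cls(grid=grid, mask=mask, values=volume[mask], name=name)


@dataclass
class SubjectFieldStack:
    """Masked per-subject volumes: the unit of every statistical analysis.

    ``data[s, c]`` is subject ``s``'s value at masked voxel column ``c``.
    Field-magnitude stacks are nonnegative; stacks of paired differences may
    carry either sign (``allow_negative=True``).
    """

    grid: Grid
    subject_ids: tuple[str, ...]
    data: np.ndarray  # (n_subjects, n_masked_voxels)
    mask: np.ndarray  # boolean volume
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.data = np.asarray(self.data, dtype=float)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject_ids must be unique")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        n_masked = int(self.mask.sum())
        if self.data.shape != (len(self.subject_ids), n_masked):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"({len(self.subject_ids)}, {n_masked})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values inside the mask")
        if not self.allow_negative and np.any(self.data < 0):
            raise ValueError("field magnitudes must be nonnegative")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def voxel_index(self) -> np.ndarray:
        """(n_masked, 3) array of (i, j, k) per column, lexicographic order."""
        return np.argwhere(self.mask)

    def map_from(self, values: np.ndarray, name: str = "") -> StatMap:
        return StatMap(grid=self.grid, mask=self.mask, values=values, name=name)

    def subset(self, indices: Sequence[int]) -> "SubjectFieldStack":
        idx = list(indices)
        return SubjectFieldStack(
            grid=self.grid,
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            data=self.data[idx],
            mask=self.mask,
            allow_negative=self.allow_negative,
        )


def _grid_of(img: nib.spatialimages.SpatialImage) -> Grid:
    return Grid(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine, dtype=float))


def read_volume(path: str | Path, expect_grid: Grid | None = None) -> tuple[np.ndarray, Grid]:
    """Read a NIfTI volume: 3D scalar, or 4D with 3 components (vector field).

    Returns the data array in file order and the file's :class:`Grid`; when
    ``expect_grid`` is given, raises :class:`GridMismatchError` unless the
    file sits on that grid.
    """
    img = nib.load(str(path))
    if img.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D image, got {img.ndim}D")
    if img.ndim == 4 and img.shape[3] != 3:
        raise ValueError(
            f"{path}: 4D input must carry exactly 3 vector components, got {img.shape[3]}"
        )
    grid = _grid_of(img)
    if expect_grid is not None:
        expect_grid.require_match(grid, what=str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    return data, grid


def read_mask(path: str | Path, expect_grid: Grid | None = None) -> tuple[np.ndarray, Grid]:
    data, grid = read_volume(path, expect_grid)
    if data.ndim != 3:
        raise ValueError(f"{path}: a mask must be 3D")
    return data > 0, grid


def build_stack(
    paths: Sequence[str | Path],
    mask_policy: str = "explicit",
    mask: np.ndarray | str | Path | None = None,
    subject_ids: Sequence[str] | None = None,
    allow_negative: bool = False,
) -> SubjectFieldStack:
    """Assemble per-subject magnitude volumes into a masked stack.

    mask_policy
        ``"explicit"`` — use the given mask (array or NIfTI path);
        ``"intersection_nonzero"`` — keep voxels strictly positive in every
        subject.
    """
    paths = list(paths)
    if len(paths) < 2:
        raise ValueError("a stack needs at least 2 subjects")
    if subject_ids is None:
        subject_ids = [Path(p).name.split(".")[0] for p in paths]

    volumes = []
    grid: Grid | None = None
    for p in paths:
        data, g = read_volume(p, expect_grid=grid)
        if data.ndim != 3:
            raise ValueError(f"{p}: stack inputs must be 3D magnitude volumes")
        grid = grid or g
        volumes.append(data)
    assert grid is not None

    if mask_policy == "intersection_nonzero":
        mask_arr = np.all(np.stack(volumes) > 0, axis=0)
    elif mask_policy == "explicit":
        if mask is None:
            raise ValueError("mask_policy='explicit' requires a mask")
        if isinstance(mask, (str, Path)):
            mask_arr, _ = read_mask(mask, expect_grid=grid)
        else:
            mask_arr = np.asarray(mask, dtype=bool)
            if mask_arr.shape != grid.shape:
                raise GridMismatchError("explicit mask shape does not match the grid")
    else:
        raise ValueError(f"unknown mask_policy {mask_policy!r}")

    return stack_from_volumes(
        volumes, grid, mask_arr, subject_ids, allow_negative=allow_negative
    )


def stack_from_volumes(
    volumes: Sequence[np.ndarray],
    grid: Grid,
    mask: np.ndarray,
    subject_ids: Sequence[str],
    allow_negative: bool = False,
) -> SubjectFieldStack:
    """Build a stack from in-memory 3D volumes sharing ``grid``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("analysis mask is empty")
    data = np.empty((len(volumes), int(mask.sum())), dtype=float)
    for s, vol in enumerate(volumes):
        vol = np.asarray(vol, dtype=float)
        if vol.shape != grid.shape:
            raise GridMismatchError("volume shape does not match the grid")
        vals = vol[mask]
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"subject {subject_ids[s]!r} has non-finite values inside the mask"
            )
        data[s] = vals
    return SubjectFieldStack(
        grid=grid,
        subject_ids=tuple(subject_ids),
        data=data,
        mask=mask,
        allow_negative=allow_negative,
    )


def write_volume(volume: np.ndarray, grid: Grid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def write_stat_map(stat_map: StatMap, path: str | Path) -> None:
    """Write a stat map as NIfTI: map values at masked voxels, 0 elsewhere."""
    write_volume(stat_map.to_volume(fill=0.0), stat_map.grid, path)
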