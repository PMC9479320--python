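"""HU-window masking, patch tiling, and mask → point-cloud conversion.

The data-preparation stage: CT attenuation patches are thresholded to the
adipose Hounsfield window (default [−190, −30] HU, endpoints inclusive — the
standard fat-segmentation convention), per-subject patches are concatenated
into one large patch by row-major tiling, and masked pixels become a planar
point cloud at their (x, y) = (column, row) pixel coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InputError

TIFF_OFFSET = 1024  # stored integer = HU + 1024 (keeps 16-bit TIFF unsigned)

__all__ = [
    "HuWindow",
    "FAT_WINDOW",
    "as_patch",
    "mask_hu",
    "concatenate_patches",
    "points_from_mask",
    "as_point_cloud",
    "read_patch_csv",
    "write_patch_csv",
    "read_patch_tiff",
    "write_patch_tiff",
    "write_mask_csv",
    "read_points_tsv",
    "write_points_tsv",
]


@dataclass(frozen=True)
class HuWindow:
    """Closed attenuation interval [lo, hi] in Hounsfield units."""

    lo: float = -190.0
    hi: float = -30.0

    def __post_init__(self):
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise InputError("window endpoints must be finite")
        if self.lo > self.hi:
            raise InputError(f"window lo={self.lo} exceeds hi={self.hi}")


FAT_WINDOW = HuWindow()


def as_patch(values) -> np.ndarray:
    """Validate and return a 2D float array of finite HU values."""
    try:
        arr = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise InputError(f"patch is not a rectangular numeric grid: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise InputError(f"patch must be a nonempty 2D grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError("patch contains non-finite values")
    return arr


def mask_hu(patch, window: HuWindow = FAT_WINDOW) -> np.ndarray:
    """Boolean mask of pixels inside the HU window (endpoints inclusive)."""
    arr = as_patch(patch)
    return (arr >= window.lo) & (arr <= window.hi)


def concatenate_patches(patches: Sequence, grid_cols: int) -> np.ndarray:
    """Tile equally-shaped patches row-major into one large patch.

    Patch k occupies tile (k // grid_cols, k % grid_cols); 36 patches of
    32×32 with ``grid_cols=6`` give a 192×192 patch.
    """
    if grid_cols < 1:
        raise InputError(f"grid_cols must be positive, got {grid_cols}")
    arrs = [as_patch(p) for p in patches]
    if not arrs:
        raise InputError("no patches to concatenate")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise InputError("patches have mixed shapes")
    if len(arrs) % grid_cols != 0:
        raise InputError(
            f"patch count {len(arrs)} not divisible by grid_cols={grid_cols}"
        )
    rows = [
        np.hstack(arrs[r * grid_cols : (r + 1) * grid_cols])
        for r in range(len(arrs) // grid_cols)
    ]
    return np.vstack(rows)


def points_from_mask(mask) -> np.ndarray:
    """Point cloud of true pixels as (x, y) = (column, row), 0-based.

    Returns a float array of shape (n, 2); an all-false mask yields (0, 2).
    """
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise InputError(f"mask must be 2D, got shape {arr.shape}")
    rows, cols = np.nonzero(arr)
    return np.column_stack([cols, rows]).astype(float)


def as_point_cloud(points) -> np.ndarray:
    """Validate a general (n, 2) point set, deduplicating with a warning."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError(f"point cloud must have shape (n, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError("point cloud contains non-finite coordinates")
    uniq, idx = np.unique(arr, axis=0, return_index=True)
    if len(uniq) != len(arr):
        warnings.warn(
            f"point cloud contained {len(arr) - len(uniq)} duplicate points; "
            "deduplicated",
            stacklevel=2,
        )
        arr = arr[np.sort(idx)]
    return arr


# ---------------------------------------------------------------------------
# File I/O: CSV numeric grids and 16-bit TIFF with a +1024 linear offset.


def read_patch_csv(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return as_patch(arr)


def write_patch_csv(patch, path: str | Path) -> None:
    np.savetxt(path, as_patch(patch), fmt="%.10g", delimiter=",")


def read_patch_tiff(path: str | Path) -> np.ndarray:
    """Read a 16-bit grayscale TIFF storing HU + 1024 as unsigned integers."""
    import tifffile

    raw = tifffile.imread(path)
    return as_patch(raw.astype(float) - TIFF_OFFSET)


def write_patch_tiff(patch, path: str | Path) -> None:
    import tifffile

    arr = as_patch(patch)
    shifted = np.round(arr + TIFF_OFFSET)
    if shifted.min() < 0 or shifted.max() > np.iinfo(np.uint16).max:
        raise InputError("patch out of range for 16-bit TIFF with +1024 offset")
    tifffile.imwrite(path, shifted.astype(np.uint16))


def write_mask_csv(mask, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mask).astype(int), fmt="%d", delimiter=",")


def write_points_tsv(points, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\n")
        for x, y in np.asarray(points, dtype=float):
            fh.write(f"{x:.10g}\t{y:.10g}\n")


def read_points_tsv(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if arr.size == 0:
        return np.empty((0, 2))
    return as_point_cloud(arr)
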