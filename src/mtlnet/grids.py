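"""Voxel grids and the containers shared across pipeline stages.

Every volume exchanged between stages carries a :class:`VolumeGrid`; stages
refuse to combine volumes that do not declare the same grid.  Grids are
axis-aligned (no oblique affines) because all synthetic data are generated
pre-aligned on a single grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class GridMismatchError(ValueError):
    """Two volumes that must share a grid declared different grids."""


@dataclass(frozen=True)
class VolumeGrid:
    """An axis-aligned 3D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along x, y, z (each >= 1).
    voxel_size_mm
        Voxel edge lengths in millimetres (each > 0).
    origin
        World-space coordinate (mm) of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 voxel-to-world affine (diagonal)."""
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        aff[:3, 3] = self.origin
        return aff

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


def check_same_grid(*grids: VolumeGrid) -> VolumeGrid:
    """Assert that all grids are identical; return the common grid."""
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridMismatchError(f"grid mismatch: {first} vs {g}")
    return first


def check_volume(data: np.ndarray, grid: VolumeGrid, name: str = "volume") -> np.ndarray:
    data = np.asarray(data)
    if data.shape[:3] != grid.shape:
        raise GridMismatchError(
            f"{name} shape {data.shape[:3]} does not match grid shape {grid.shape}"
        )
    return data


@dataclass
class BoldRun:
    """A 4D BOLD voxel time-series on a named grid.

    ``data`` is indexed (x, y, z, t); ``tr_s`` is the repetition time in
    seconds (2.382 s for the default synthetic sequence).
    """

    data: np.ndarray
    grid: VolumeGrid
    tr_s: float
    subject_id: str = "sub-00"
    visit_index: int = 1
    sequence_variant: int = 0

    def __post_init__(self) -> None:
        self.data = check_volume(self.data, self.grid, "BOLD data")
        if self.data.ndim != 4 or self.data.shape[3] < 2:
            raise ValueError("BOLD data must be 4D with at least 2 volumes")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class ConnMap:
    """A 3D per-voxel seed-connectivity image.

    ``scale`` is ``"pearson_r"`` (values clipped to [-1, 1], NaN outside the
    analysis mask) or ``"fisher_z"``.  ``smoothed_fwhm_mm`` is ``None`` for
    unsmoothed maps; extraction operations require unsmoothed input.
    """

    data: np.ndarray
    grid: VolumeGrid
    seed_label: str
    scale: str = "pearson_r"
    smoothed_fwhm_mm: Optional[float] = None
    subject_id: str = "sub-00"
    visit_index: int = 1

    def __post_init__(self) -> None:
        self.data = check_volume(np.asarray(self.data, dtype=float), self.grid, "ConnMap")
        if self.data.ndim != 3:
            raise ValueError("ConnMap data must be 3D")
        if self.scale not in ("pearson_r", "fisher_z"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "pearson_r":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("pearson_r values must lie in [-1, 1]")


@dataclass
class SeedRoi:
    """A binary seed region (perirhinal 'PRC' or parahippocampal 'PHC')."""

    label: str
    voxels: np.ndarray
    grid: VolumeGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.grid is not None:
            check_volume(self.voxels, self.grid, f"seed {self.label}")
        if not self.voxels.any():
            raise ValueError(f"seed ROI {self.label!r} is empty")


@dataclass
class SegmentationSet:
    """Tissue probability maps and brain mask, all on one grid."""

    gm_t1: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    gm_t2star: np.ndarray
    brain_mask: np.ndarray
    grid: VolumeGrid

    def __post_init__(self) -> None:
        for name in ("gm_t1", "wm", "csf", "gm_t2star"):
            vol = check_volume(np.asarray(getattr(self, name), dtype=float), self.grid, name)
            if vol.min() < 0 or vol.max() > 1:
                raise ValueError(f"{name} probabilities must lie in [0, 1]")
            setattr(self, name, vol)
        self.brain_mask = check_volume(
            np.asarray(self.brain_mask, dtype=bool), self.grid, "brain_mask"
        )
        if np.any((self.gm_t1 > 0) & ~self.brain_mask):
            raise ValueError("brain_mask must contain every voxel with gm_t1 > 0")
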