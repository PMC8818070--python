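"""Domain types and elementary I/O for SUV-calibrated PET volumes.

The package operates on brain-extracted amino-acid PET volumes whose voxel
values are standardised uptake values (SUV): tracer activity normalised by
injected dose and body weight, hence dimensionless.  Everything downstream
(region growing, mirroring, tumour-to-brain-ratio normalisation) works on
three aligned objects:

* :class:`SUVImage` — the 3D scalar volume plus voxel spacing in mm and the
  index of the grid axis whose midplane is the anatomical mid-sagittal
  (anterior–posterior) plane.  Inputs are assumed rigidly aligned so that the
  left–right axis coincides with a grid axis.
* :class:`VoxelMask` — a boolean volume on the same grid (brain mask, tumour
  volume, background reference region, crescent VOI).
* :class:`SeedSet` — reader-supplied voxel coordinates inside high-uptake
  lesions; the only manual input of the mirror-image method.

Coordinates are 0-based voxel indices throughout.  Volumes are reported in
cm³ using the spacing stored in the NIfTI header; spacing is never assumed
isotropic.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import nibabel as nib
import numpy as np

__all__ = [
    "FetMirrorError",
    "EmptyReferenceError",
    "SeedError",
    "SUVImage",
    "VoxelMask",
    "SeedSet",
    "TBRMap",
    "read_suv_image",
    "read_mask",
    "write_image",
    "write_mask",
    "voi_volume_cm3",
    "voi_mean",
]

DEFAULT_MIDLINE_AXIS = 0


class FetMirrorError(Exception):
    """Base class for all package-specific failures."""


class EmptyReferenceError(FetMirrorError):
    """Raised when a background reference region ends up with no voxels."""


class SeedError(FetMirrorError):
    """Raised when a seed violates its contract (out of bounds, sub-threshold...)."""


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive and finite, got {spacing}")
    return spacing


@dataclass
class SUVImage:
    """3D scalar volume in SUV units with voxel geometry.

    Parameters
    ----------
    voxels
        3D array of finite, non-negative SUV values.
    spacing
        Voxel edge lengths in mm, one per axis.
    midline_axis
        Axis whose midplane is the mid-sagittal plane (default 0).
    affine
        Optional 4x4 voxel-to-world affine carried through I/O so outputs
        keep the input geometry; not used by any computation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    midline_axis: int = DEFAULT_MIDLINE_AXIS
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.voxels.ndim}D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("SUV volume contains non-finite values")
        if np.any(self.voxels < 0):
            raise ValueError("SUV volume contains negative values")
        self.spacing = _check_spacing(self.spacing)
        if self.midline_axis not in (0, 1, 2):
            raise ValueError(f"midline_axis must be 0, 1 or 2, got {self.midline_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VoxelMask:
    """Binary volume on the same grid as its parent image."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.voxels.ndim}D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    @property
    def volume_cm3(self) -> float:
        return voi_volume_cm3(self)

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclass
class SeedSet:
    """Non-empty, duplicate-free set of 0-based voxel coordinates."""

    seeds: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        coords = []
        for s in self.seeds:
            c = tuple(int(v) for v in s)
            if len(c) != 3:
                raise ValueError(f"seed must have 3 coordinates, got {s!r}")
            coords.append(c)
        if not coords:
            raise ValueError("seed set is empty")
        if len(set(coords)) != len(coords):
            raise ValueError("seed set contains duplicate coordinates")
        self.seeds = coords

    def __iter__(self):
        return iter(self.seeds)

    def __len__(self) -> int:
        return len(self.seeds)

    def validate_against(self, image: SUVImage, brain: VoxelMask | None = None) -> None:
        """Check every seed is inside the image bounds (and brain, if given)."""
        for s in self.seeds:
            if any(c < 0 or c >= n for c, n in zip(s, image.shape)):
                raise SeedError(f"seed {s} outside image bounds {image.shape}")
            if brain is not None and not brain.voxels[s]:
                raise SeedError(f"seed {s} outside the brain mask")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SeedSet":
        """Read a JSON list of [x, y, z] integer triples."""
        with open(path) as fh:
            data = json.load(fh)
        if isinstance(data, dict) and "seeds" in data:
            data = data["seeds"]
        return cls([tuple(row) for row in data])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SeedSet":
        """Read a single-header CSV with columns x, y, z."""
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls([(int(r["x"]), int(r["y"]), int(r["z"])) for r in rows])

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump([list(s) for s in self.seeds], fh)


@dataclass
class TBRMap:
    """Tumour-to-brain-ratio map: SUV image divided by a background mean."""

    voxels: np.ndarray
    normaliser: float
    spacing: tuple[float, float, float]
    midline_axis: int = DEFAULT_MIDLINE_AXIS

    def __post_init__(self) -> None:
        if not np.isfinite(self.normaliser) or self.normaliser <= 0:
            raise ValueError(f"TBR normaliser must be positive, got {self.normaliser}")
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_suv_image(path: Union[str, Path], midline_axis: int = DEFAULT_MIDLINE_AXIS) -> SUVImage:
    """Load a 3D NIfTI-1 SUV volume; spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    spacing = img.header.get_zooms()[:3]
    return SUVImage(
        voxels=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        midline_axis=midline_axis,
        affine=np.asarray(img.affine),
    )


def read_mask(path: Union[str, Path]) -> VoxelMask:
    """Load a binary NIfTI-1 mask (any nonzero voxel counts as true)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D in {path}")
    return VoxelMask(voxels=data != 0, spacing=img.header.get_zooms()[:3])


def _affine_for(spacing: Sequence[float], affine: np.ndarray | None) -> np.ndarray:
    if affine is not None:
        return np.asarray(affine)
    return np.diag(list(spacing) + [1.0])


def write_image(image: SUVImage, path: Union[str, Path]) -> None:
    nii = nib.Nifti1Image(image.voxels.astype(np.float64), _affine_for(image.spacing, image.affine))
    nii.header.set_zooms(image.spacing)
    nib.save(nii, str(path))


def write_mask(mask: VoxelMask, path: Union[str, Path], affine: np.ndarray | None = None) -> None:
    # uint8 0/1 is the de-facto interchange dialect for segmentations
    nii = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine_for(mask.spacing, affine))
    nii.header.set_zooms(mask.spacing)
    nib.save(nii, str(path))


# ---------------------------------------------------------------------------
# Elementary measurements
# ---------------------------------------------------------------------------

def voi_volume_cm3(mask: VoxelMask) -> float:
    """Volume of the true voxels in cm³ (voxel count × voxel volume mm³ / 1000)."""
    return mask.n_voxels * float(np.prod(mask.spacing)) / 1000.0


def voi_mean(image: Union[SUVImage, TBRMap], mask: VoxelMask) -> float:
    """Arithmetic mean of image values over the mask.

    Raises
    ------
    EmptyReferenceError
        If the mask has no true voxel — the failure signal for degenerate
        mirroring (e.g. a tumour spanning the whole midline).
    """
    if image.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {image.shape} vs mask {mask.shape}")
    if mask.is_empty():
        raise EmptyReferenceError("reference region is empty")
    return float(image.voxels[mask.voxels].mean())
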