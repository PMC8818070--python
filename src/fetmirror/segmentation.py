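"""Geometric primitives: threshold-connected region growing and midline mirroring.

Region growing from a seed with a fixed threshold is exactly the connected
component of the supra-threshold voxel set that contains the seed, so it is
computed with one connected-component labelling pass rather than an explicit
flood fill.  Two consequences matter downstream:

* **Seed invariance** — any seed inside a given component yields the identical
  mask, which is what drives the mirror-image pipeline's zero intra-reader
  variability.
* **Threshold monotonicity** — raising the threshold can only shrink the
  grown region (same seeds).

Mirroring maps index ``i`` along the midline axis to ``N - 1 - i``: for an
even-sized axis this reflects about the inter-voxel midplane, for an odd-sized
axis the central slab is fixed.  Either way the operation is an involution and
preserves voxel count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .core import (
    EmptyReferenceError,
    SeedError,
    SeedSet,
    SUVImage,
    TBRMap,
    VoxelMask,
)

__all__ = ["GrowConfig", "region_grow", "mirror_mask", "exclude_overlap"]


@dataclass
class GrowConfig:
    """Threshold (inclusive, in the units of the map grown on) and connectivity.

    connectivity 6 = faces only; 26 = faces + edges + corners (default: PET
    uptake blobs are often only obliquely contiguous at the voxel level).
    """

    threshold: float
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)


def region_grow(
    map_: Union[SUVImage, TBRMap],
    seeds: SeedSet,
    cfg: GrowConfig,
    brain: VoxelMask,
) -> VoxelMask:
    """Grow the union of connected supra-threshold components containing the seeds.

    A voxel belongs to the result iff its value is >= ``cfg.threshold``, it lies
    inside the brain mask, and it is connected (under ``cfg.connectivity``) to
    at least one seed through voxels that also satisfy both conditions.

    Raises
    ------
    SeedError
        If a seed lies outside the image/brain or its value is below the
        threshold (naming the offending seed).
    """
    if map_.shape != brain.shape:
        raise ValueError(f"shape mismatch: map {map_.shape} vs brain {brain.shape}")
    values = map_.voxels
    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, map_.shape)):
            raise SeedError(f"seed {s} outside image bounds {map_.shape}")
        if not brain.voxels[s]:
            raise SeedError(f"seed {s} outside the brain mask")
        if values[s] < cfg.threshold:
            raise SeedError(
                f"seed below threshold: value {values[s]:.4g} at {s} < {cfg.threshold}"
            )

    supra = (values >= cfg.threshold) & brain.voxels
    labels, _ = ndimage.label(supra, structure=cfg.structure)
    wanted = {labels[s] for s in seeds}
    wanted.discard(0)  # cannot happen given the seed checks, but keep the guard
    out = np.isin(labels, sorted(wanted))
    return VoxelMask(voxels=out, spacing=brain.spacing)


def mirror_mask(mask: VoxelMask, midline_axis: int) -> VoxelMask:
    """Reflect a mask across the midplane of ``midline_axis`` (i -> N-1-i)."""
    if mask.is_empty():
        raise ValueError("cannot mirror an empty mask")
    if midline_axis not in (0, 1, 2):
        raise ValueError(f"midline_axis must be 0, 1 or 2, got {midline_axis}")
    return VoxelMask(voxels=np.flip(mask.voxels, axis=midline_axis), spacing=mask.spacing)


def exclude_overlap(ctrl: VoxelMask, btv: VoxelMask, brain: VoxelMask) -> VoxelMask:
    """Remove tumour overlap and out-of-brain voxels from a reference region.

    Returns ``ctrl AND NOT btv AND brain``.  Mirrored voxels falling outside
    the brain are clipped because the reference must be plausible tissue.

    Raises
    ------
    EmptyReferenceError
        If nothing remains — the degenerate case of a tumour heavily involving
        the midline, which this method deliberately refuses to approximate.
    """
    if not (ctrl.shape == btv.shape == brain.shape):
        raise ValueError(
            f"shape mismatch: ctrl {ctrl.shape}, btv {btv.shape}, brain {brain.shape}"
        )
    out = ctrl.voxels & ~btv.voxels & brain.voxels
    if not out.any():
        raise EmptyReferenceError("reference region fully excluded")
    return VoxelMask(voxels=out, spacing=ctrl.spacing)
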