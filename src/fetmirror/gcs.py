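"""Guided crescent-shape (gCS) comparator pipeline — single pass, no iteration.

The current manual standard for background definition in amino-acid PET: the
reader draws a crescent-shaped reference VOI in the contralateral hemisphere
(spanning grey and white matter, avoiding ventricles and venous sinuses) per
published drawing guidelines.  The crescent's mean SUV normalises the image
into a TBR map and the tumour volume is grown once at the TBR threshold.

The crescent VOI is consumed as a mask file; the drawing rules themselves are
manual guidelines and are not encoded here (the phantom module provides a
simulated-reader generator for testing).  Normalisation is solely determined
by the drawn crescent, so — unlike the mirror-image method — multifocal
disease does not influence the reference region.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import SeedSet, SUVImage, VoxelMask, voi_mean, voi_volume_cm3
from .mi import MIConfig, make_tbr_map
from .segmentation import GrowConfig, region_grow

__all__ = ["GCSResult", "run_gcs"]


@dataclass
class GCSResult:
    btv: VoxelMask
    ctrl: VoxelMask
    ctrl_suv_mean: float
    btv_volume_cm3: float


def run_gcs(
    image: SUVImage,
    brain: VoxelMask,
    seeds: SeedSet,
    crescent: VoxelMask,
    cfg: MIConfig | None = None,
) -> GCSResult:
    """Normalise by the crescent mean and grow the tumour volume once.

    Raises
    ------
    EmptyReferenceError
        If the crescent mask is empty.
    ValueError
        If the crescent leaks outside the brain mask — a drawn VOI outside
        the brain indicates broken inputs and is rejected, not clipped.
    SeedError
        If a seed falls below the TBR threshold after normalisation.
    """
    cfg = cfg or MIConfig()
    seeds.validate_against(image, brain)
    if crescent.shape != image.shape:
        raise ValueError(f"shape mismatch: crescent {crescent.shape} vs image {image.shape}")
    if (crescent.voxels & ~brain.voxels).any():
        raise ValueError("crescent VOI extends outside the brain mask")

    s = voi_mean(image, crescent)  # raises EmptyReferenceError on empty crescent
    tbr = make_tbr_map(image, s)
    btv = region_grow(tbr, seeds, GrowConfig(cfg.tbr_threshold, cfg.connectivity), brain)
    return GCSResult(
        btv=btv,
        ctrl=crescent,
        ctrl_suv_mean=s,
        btv_volume_cm3=voi_volume_cm3(btv),
    )
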