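"""Iterative mirror-image (MI) pipeline for background activity and BTV.

The mirror-image method replaces the manual drawing of a background reference
region by an automatic construction: the tumour segmentation is reflected
across the mid-sagittal plane into the contralateral hemisphere, and the mean
SUV of that mirror region normalises the image into a tumour-to-brain-ratio
(TBR) map.  Because the tumour segmentation itself depends on the TBR map,
the construction iterates:

0. ``BTV_0`` = region growing on the SUV image at threshold 2.2 from the
   reader seed(s).
k. ``CTRL_k`` = mirror of ``BTV_k`` with tumour overlap and out-of-brain
   voxels removed; ``S_k`` = mean SUV over ``CTRL_k``; ``BTV_{k+1}`` = region
   growing on the TBR map ``image / S_k`` at threshold 1.9.

The loop stops when ``|vol(BTV_{k+1}) - vol(CTRL_k)| <= 0.2 cm³``.  After
convergence the reference region is rebuilt once against the final BTV
(overlap removal happens after convergence) and the reported background mean
is recomputed on it; the BTV is not regrown after this final exclusion.

Multiple seeds (multifocal disease) grow a union BTV whose mirror is a union
reference region, so each lesion contributes background from its own
contralateral neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (
    EmptyReferenceError,
    SeedSet,
    SUVImage,
    TBRMap,
    VoxelMask,
    voi_mean,
    voi_volume_cm3,
)
from .segmentation import GrowConfig, exclude_overlap, mirror_mask, region_grow

logger = logging.getLogger(__name__)

__all__ = ["MIConfig", "IterationRecord", "MIResult", "make_tbr_map", "run_mi"]


@dataclass
class MIConfig:
    """Parameters of the mirror-image optimisation.

    suv_threshold
        Region-growing cut-off on the raw SUV image for the initial tumour
        segmentation (default 2.2, the published recurrent-glioma cut-off).
    tbr_threshold
        Cut-off on the TBR map for all subsequent growths (default 1.9).
    volume_tolerance_cm3
        Convergence band between the new BTV volume and the previous
        reference-region volume (default 0.2 cm³).
    exclude_hot_from_ctrl
        Optionally also remove any supra-threshold TBR voxel from the final
        reference region, not just BTV overlap (default off: the baseline
        method removes BTV overlap only).
    """

    suv_threshold: float = 2.2
    tbr_threshold: float = 1.9
    volume_tolerance_cm3: float = 0.2
    max_iterations: int = 50
    connectivity: int = 26
    exclude_hot_from_ctrl: bool = False

    def __post_init__(self) -> None:
        if self.suv_threshold <= 0 or self.tbr_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.volume_tolerance_cm3 < 0:
            raise ValueError("volume tolerance must be non-negative")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    iteration: int
    btv_volume_cm3: float
    ctrl_volume_cm3: float
    ctrl_suv_mean: float
    next_btv_volume_cm3: float


@dataclass
class MIResult:
    btv: VoxelMask
    ctrl: VoxelMask
    ctrl_suv_mean: float
    btv_volume_cm3: float
    converged: bool
    trace: list[IterationRecord] = field(default_factory=list)

    def trace_dicts(self) -> list[dict]:
        return [vars(r).copy() for r in self.trace]


def make_tbr_map(image: SUVImage, ctrl_suv_mean: float) -> TBRMap:
    """Normalise an SUV image by a background mean into a TBR map."""
    if not np.isfinite(ctrl_suv_mean) or ctrl_suv_mean <= 0:
        raise ValueError(f"background SUV mean must be positive, got {ctrl_suv_mean}")
    return TBRMap(
        voxels=image.voxels / ctrl_suv_mean,
        normaliser=float(ctrl_suv_mean),
        spacing=image.spacing,
        midline_axis=image.midline_axis,
    )


def run_mi(
    image: SUVImage,
    brain: VoxelMask,
    seeds: SeedSet,
    cfg: MIConfig | None = None,
) -> MIResult:
    """Run the mirror-image optimisation from seed(s) to a converged result.

    Raises
    ------
    SeedError
        If a seed is out of bounds, outside the brain, or below the SUV
        threshold on the input image.
    EmptyReferenceError
        If at any iteration the mirrored reference region is entirely removed
        by overlap/brain exclusion (midline-dominated tumours are out of this
        method's domain and fail loudly); re-raised with the iteration index.
    """
    cfg = cfg or MIConfig()
    seeds.validate_against(image, brain)

    grow_suv = GrowConfig(cfg.suv_threshold, cfg.connectivity)
    grow_tbr = GrowConfig(cfg.tbr_threshold, cfg.connectivity)

    btv = region_grow(image, seeds, grow_suv, brain)
    trace: list[IterationRecord] = []
    converged = False
    tbr: TBRMap | None = None

    for k in range(cfg.max_iterations):
        try:
            ctrl = exclude_overlap(mirror_mask(btv, image.midline_axis), btv, brain)
        except EmptyReferenceError as err:
            raise EmptyReferenceError(f"{err} (iteration {k})") from err
        s_k = voi_mean(image, ctrl)
        tbr = make_tbr_map(image, s_k)
        next_btv = region_grow(tbr, seeds, grow_tbr, brain)

        rec = IterationRecord(
            iteration=k,
            btv_volume_cm3=voi_volume_cm3(btv),
            ctrl_volume_cm3=voi_volume_cm3(ctrl),
            ctrl_suv_mean=s_k,
            next_btv_volume_cm3=voi_volume_cm3(next_btv),
        )
        trace.append(rec)
        logger.info(
            "iteration %d: vol(BTV)=%.3f cm3, vol(CTRL)=%.3f cm3, S=%.4f, vol(BTV')=%.3f cm3",
            k, rec.btv_volume_cm3, rec.ctrl_volume_cm3, s_k, rec.next_btv_volume_cm3,
        )

        btv = next_btv
        if abs(rec.next_btv_volume_cm3 - rec.ctrl_volume_cm3) <= cfg.volume_tolerance_cm3:
            converged = True
            break
        # two-cycle detector: volume oscillating between two values
        if len(trace) >= 3 and (
            trace[-1].btv_volume_cm3 == trace[-3].btv_volume_cm3
            and trace[-1].btv_volume_cm3 != trace[-2].btv_volume_cm3
        ):
            logger.warning("BTV volume is alternating between two values (possible 2-cycle)")

    if not converged:
        logger.warning("mirror-image optimisation did not converge in %d iterations", cfg.max_iterations)

    # overlap removal happens once convergence is reached, against the final BTV
    try:
        final_ctrl = exclude_overlap(mirror_mask(btv, image.midline_axis), btv, brain)
    except EmptyReferenceError as err:
        raise EmptyReferenceError(f"{err} (final reference region)") from err
    if cfg.exclude_hot_from_ctrl and tbr is not None:
        keep = final_ctrl.voxels & ~(tbr.voxels >= cfg.tbr_threshold)
        if not keep.any():
            raise EmptyReferenceError("reference region fully excluded (final reference region)")
        final_ctrl = VoxelMask(voxels=keep, spacing=final_ctrl.spacing)

    return MIResult(
        btv=btv,
        ctrl=final_ctrl,
        ctrl_suv_mean=voi_mean(image, final_ctrl),
        btv_volume_cm3=voi_volume_cm3(btv),
        converged=converged,
        trace=trace,
    )
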