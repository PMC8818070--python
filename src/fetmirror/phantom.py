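"""Synthetic brain phantoms and simulated reader inputs.

Real amino-acid PET reader studies need patients and hours of reader time;
this module builds the in-silico stand-in: an ellipsoidal "brain" with
near-uniform background uptake (SUV ~ 1), one or more high-uptake lesions
(SUV well above the 2.2 growth threshold) and exact left-right symmetry of
the brain mask about the mid-sagittal grid axis, so mirrored reference
regions always land in valid tissue.  Optional additive Gaussian noise
(clipped at zero) models statistical image noise; spatially correlated
PET noise and anatomical texture are deliberately not modelled — the
phantoms target the variability properties of the delineation methods,
not image realism.

A simulated-reader generator produces the manual inputs of a reader study
(default 7 readers x 6 repeats): seed voxels sampled uniformly inside the
true lesion, and crescent-shaped background VOIs with jittered placement
and, optionally, a controlled contamination fraction drawn from an
elevated-uptake rim around the lesion — the mechanism by which real readers
accidentally include tissue with above-background uptake.

Everything is deterministic given the spec's ``rng_seed``; per-(reader,
repeat) streams are derived from it so partial reruns match full runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import SeedSet, SUVImage, VoxelMask

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "Phantom",
    "generate_phantom",
    "standard_phantom",
    "random_phantom_battery",
    "SimulatedReaderSpec",
    "ReaderInput",
    "simulate_reader_inputs",
]


@dataclass
class LesionSpec:
    """One lesion: centre offset from the grid centre in mm, size, uptake.

    ``rim_width_mm``/``rim_suv`` add a concentric shell of elevated (but
    sub-lesion) uptake around the lesion, used to exercise threshold
    behaviour and crescent contamination.
    """

    centre_mm: tuple[float, float, float]
    radius_mm: float = 10.0
    suv: float = 3.0
    shape: str = "sphere"
    semi_axes_mm: tuple[float, float, float] | None = None
    rim_width_mm: float = 0.0
    rim_suv: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"lesion shape must be 'sphere' or 'ellipsoid', got {self.shape!r}")
        if self.shape == "ellipsoid" and self.semi_axes_mm is None:
            raise ValueError("ellipsoid lesion needs semi_axes_mm")
        if self.rim_width_mm > 0 and self.rim_suv is None:
            raise ValueError("rim_width_mm > 0 requires rim_suv")


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (90, 108, 90)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    brain_semiaxes_mm: tuple[float, float, float] = (80.0, 100.0, 80.0)
    background_suv: float = 1.0
    noise_sd: float = 0.0
    lesions: list[LesionSpec] = field(default_factory=list)
    rng_seed: int = 0
    midline_axis: int = 0
    allow_lesion_outside_brain: bool = False

    def __post_init__(self) -> None:
        if self.background_suv <= 0:
            raise ValueError("background SUV must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for les in self.lesions:
            if les.suv <= self.background_suv:
                raise ValueError(
                    f"lesion SUV {les.suv} must exceed background {self.background_suv}"
                )


@dataclass
class Phantom:
    image: SUVImage
    brain: VoxelMask
    true_lesions: list[VoxelMask]
    rims: list[VoxelMask]
    spec: PhantomSpec


def _mm_grids(shape, spacing):
    """Per-axis voxel-centre coordinates in mm, centred on the grid midpoint."""
    return [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * s
        for n, s in zip(shape, spacing)
    ]


def _lesion_masks(spec: PhantomSpec):
    gx, gy, gz = _mm_grids(spec.shape, spec.spacing)
    lesions, rims = [], []
    for les in spec.lesions:
        cx, cy, cz = les.centre_mm
        if les.shape == "sphere":
            ax = ay = az = les.radius_mm
        else:
            ax, ay, az = les.semi_axes_mm  # type: ignore[misc]
        d2 = (
            ((gx - cx)[:, None, None] / ax) ** 2
            + ((gy - cy)[None, :, None] / ay) ** 2
            + ((gz - cz)[None, None, :] / az) ** 2
        )
        core = d2 <= 1.0
        lesions.append(core)
        if les.rim_width_mm > 0:
            w = les.rim_width_mm
            d2_out = (
                ((gx - cx)[:, None, None] / (ax + w)) ** 2
                + ((gy - cy)[None, :, None] / (ay + w)) ** 2
                + ((gz - cz)[None, None, :] / (az + w)) ** 2
            )
            rims.append((d2_out <= 1.0) & ~core)
        else:
            rims.append(np.zeros(spec.shape, dtype=bool))
    return lesions, rims


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom volume, brain mask and ground-truth lesion masks.

    The brain ellipsoid is centred on the grid midpoint, so the brain mask is
    exactly symmetric under reflection about any axis midplane.  Lesion and
    rim uptake overwrite the background; Gaussian noise (if any) is then
    added over the whole brain and clipped at zero.  Deterministic given
    ``spec.rng_seed``.
    """
    gx, gy, gz = _mm_grids(spec.shape, spec.spacing)
    bx, by, bz = spec.brain_semiaxes_mm
    brain = (
        (gx[:, None, None] / bx) ** 2
        + (gy[None, :, None] / by) ** 2
        + (gz[None, None, :] / bz) ** 2
    ) <= 1.0

    lesion_masks, rim_masks = _lesion_masks(spec)
    for i, (core, rim) in enumerate(zip(lesion_masks, rim_masks)):
        if not core.any():
            raise ValueError(f"lesion {i} covers no voxel (radius below voxel size?)")
        outside = (core | rim) & ~brain
        if outside.any() and not spec.allow_lesion_outside_brain:
            raise ValueError(
                f"lesion {i} extends outside the brain "
                "(set allow_lesion_outside_brain to permit edge-case fixtures)"
            )

    img = np.zeros(spec.shape, dtype=np.float64)
    img[brain] = spec.background_suv
    for les, core, rim in zip(spec.lesions, lesion_masks, rim_masks):
        if les.rim_width_mm > 0:
            img[rim & brain] = les.rim_suv
        img[core & brain] = les.suv
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
        img[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        np.clip(img, 0.0, None, out=img)

    image = SUVImage(
        voxels=img, spacing=spec.spacing, midline_axis=spec.midline_axis
    )
    return Phantom(
        image=image,
        brain=VoxelMask(voxels=brain, spacing=spec.spacing),
        true_lesions=[VoxelMask(voxels=m & brain, spacing=spec.spacing) for m in lesion_masks],
        rims=[VoxelMask(voxels=m & brain, spacing=spec.spacing) for m in rim_masks],
        spec=spec,
    )


def standard_phantom(
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    lesion_radius_mm: float = 10.0,
    lesion_suv: float = 3.0,
    lesion_offset_mm: tuple[float, float, float] = (40.0, 0.0, 0.0),
    rim_width_mm: float = 0.0,
    rim_suv: float | None = None,
) -> Phantom:
    """The default study phantom: one off-midline spherical lesion.

    Background SUV 1.0, lesion SUV 3.0 at 40 mm off the mid-sagittal plane —
    lesion uptake clears both the SUV 2.2 and TBR 1.9 thresholds while the
    background clears neither.
    """
    spec = PhantomSpec(
        lesions=[
            LesionSpec(
                centre_mm=lesion_offset_mm,
                radius_mm=lesion_radius_mm,
                suv=lesion_suv,
                rim_width_mm=rim_width_mm,
                rim_suv=rim_suv,
            )
        ],
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )
    return generate_phantom(spec)


def random_phantom_battery(
    n: int,
    rng_seed: int = 0,
    radius_range_mm: tuple[float, float] = (6.0, 14.0),
    noise_sd: float = 0.05,
) -> list[Phantom]:
    """A battery of phantoms with randomised lesion size and off-midline position.

    Lesion radius is uniform over ``radius_range_mm``; the centre is jittered
    off the midline (30-50 mm lateral, ±20 mm in the other axes) so the
    mirrored reference always lands in contralateral tissue; mild Gaussian
    noise is added.  Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 0xBA77E)))
    phantoms = []
    for i in range(n):
        radius = float(rng.uniform(*radius_range_mm))
        side = 1.0 if rng.random() < 0.5 else -1.0
        centre = (
            side * float(rng.uniform(30.0, 50.0)),
            float(rng.uniform(-20.0, 20.0)),
            float(rng.uniform(-20.0, 20.0)),
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        phantoms.append(
            standard_phantom(
                noise_sd=noise_sd,
                rng_seed=sub_seed,
                lesion_radius_mm=radius,
                lesion_offset_mm=centre,
            )
        )
    return phantoms


# ---------------------------------------------------------------------------
# Simulated readers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReaderSpec:
    """Rules generating the manual inputs of a simulated reader study.

    Seeds: one voxel per lesion per repeat, uniform over the lesion voxels at
    or above ``seed_suv_threshold``, distinct across a reader's repeats when
    the lesion is large enough.  Crescents: a contiguous background shell
    (inner/outer radius in mm) centred near the mirror of the lesion centroid
    in the contralateral hemisphere, with positional and extent jitter;
    ``contamination_fraction`` > 0 swaps that fraction of crescent voxels for
    elevated-uptake rim voxels (the phantom must then have a rim).
    """

    n_readers: int = 7
    n_repeats: int = 6
    seed_suv_threshold: float = 2.2
    crescent_inner_mm: float = 10.0
    crescent_outer_mm: float = 20.0
    crescent_jitter_mm: float = 6.0
    crescent_extent_jitter: float = 0.15
    contamination_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_readers < 1 or self.n_repeats < 1:
            raise ValueError("need at least one reader and one repeat")
        if not (0 <= self.contamination_fraction < 0.6):
            raise ValueError("contamination_fraction must be in [0, 0.6)")
        if self.crescent_inner_mm >= self.crescent_outer_mm:
            raise ValueError("crescent inner radius must be below the outer radius")


@dataclass
class ReaderInput:
    seeds: SeedSet
    crescent: VoxelMask | None = None


def _reader_rng(base_seed: int, reader: int, repeat: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((base_seed, reader, repeat)))


def _sample_seed_indices(rng, n_candidates: int, n_repeats: int) -> np.ndarray:
    if n_candidates >= n_repeats:
        return rng.choice(n_candidates, size=n_repeats, replace=False)
    warnings.warn(
        f"lesion has only {n_candidates} seedable voxels for {n_repeats} repeats; "
        "sampling seeds with replacement",
        stacklevel=3,
    )
    return rng.choice(n_candidates, size=n_repeats, replace=True)


def _crescent_for(
    phantom: Phantom, spec: SimulatedReaderSpec, rng: np.random.Generator
) -> VoxelMask:
    ph_spec = phantom.spec
    axis = ph_spec.midline_axis
    grids = _mm_grids(ph_spec.shape, ph_spec.spacing)

    lesion = phantom.true_lesions[0].voxels
    idx = np.argwhere(lesion)
    centroid_mm = np.array(
        [grids[a][idx[:, a]].mean() for a in range(3)]
    )
    if abs(centroid_mm[axis]) < 1e-9:
        raise ValueError("cannot place a contralateral crescent for a midline lesion")
    mirror_centre = centroid_mm.copy()
    mirror_centre[axis] = -mirror_centre[axis]

    centre = mirror_centre + rng.uniform(-spec.crescent_jitter_mm, spec.crescent_jitter_mm, 3)
    u = 1.0 + rng.uniform(-spec.crescent_extent_jitter, spec.crescent_extent_jitter)
    r_in, r_out = spec.crescent_inner_mm * u, spec.crescent_outer_mm * u

    d2 = (
        (grids[0][:, None, None] - centre[0]) ** 2
        + (grids[1][None, :, None] - centre[1]) ** 2
        + (grids[2][None, None, :] - centre[2]) ** 2
    )
    shell = (d2 >= r_in**2) & (d2 <= r_out**2)

    # restrict to the hemisphere opposite the lesion
    side = np.sign(centroid_mm[axis])
    coord = grids[axis]
    hemi_1d = (coord * side) < 0
    hemi = np.zeros(ph_spec.shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = hemi_1d
    hemi[tuple(sl)] = True

    exclude = np.zeros(ph_spec.shape, dtype=bool)
    for m in phantom.true_lesions + phantom.rims:
        exclude |= m.voxels
    crescent = shell & phantom.brain.voxels & hemi & ~exclude
    if not crescent.any():
        raise ValueError("simulated crescent is empty; check phantom geometry")

    # keep the largest connected piece so the drawn VOI is contiguous
    labels, n = ndimage.label(crescent, structure=ndimage.generate_binary_structure(3, 3))
    if n > 1:
        sizes = ndimage.sum_labels(crescent, labels, index=np.arange(1, n + 1))
        crescent = labels == (1 + int(np.argmax(sizes)))

    if spec.contamination_fraction > 0:
        rim = np.zeros(ph_spec.shape, dtype=bool)
        for m in phantom.rims:
            rim |= m.voxels
        if not rim.any():
            raise ValueError("crescent contamination requested but the phantom has no rim")
        f = spec.contamination_fraction * rng.uniform(0.5, 1.5)
        rim_idx = np.argwhere(rim)
        n_total = int(crescent.sum())
        k = int(round(f * n_total))
        if k > len(rim_idx):
            # rim pool too small at this size: shrink the crescent so the
            # requested mixture fraction is preserved exactly
            n_total = int(len(rim_idx) / f)
            k = int(round(f * n_total))
            cres_idx = np.argwhere(crescent)
            keep = cres_idx[rng.choice(len(cres_idx), size=n_total, replace=False)]
            crescent = np.zeros_like(crescent)
            crescent[tuple(keep.T)] = True
        if k > 0:
            cres_idx = np.argwhere(crescent)
            drop = cres_idx[rng.choice(len(cres_idx), size=k, replace=False)]
            take = rim_idx[rng.choice(len(rim_idx), size=k, replace=False)]
            crescent[tuple(drop.T)] = False
            crescent[tuple(take.T)] = True

    return VoxelMask(voxels=crescent, spacing=ph_spec.spacing)


def simulate_reader_inputs(
    phantom: Phantom, spec: SimulatedReaderSpec | None = None
) -> list[list[ReaderInput]]:
    """Generate (seed set, crescent) pairs for every reader x repeat.

    Returns ``inputs[reader][repeat]``.  Every seed lies inside a true lesion
    at or above the seeding SUV threshold; every crescent lies inside the
    brain and, at zero contamination, contains only pure background voxels.
    """
    spec = spec or SimulatedReaderSpec()
    if not phantom.true_lesions:
        raise ValueError("phantom has no lesion to seed")

    img = phantom.image.voxels
    lesion_candidates = []
    for i, lesion in enumerate(phantom.true_lesions):
        cand = np.argwhere(lesion.voxels & (img >= spec.seed_suv_threshold))
        if len(cand) == 0:
            raise ValueError(f"lesion {i} has no voxel at or above the seeding threshold")
        lesion_candidates.append(cand)

    readers: list[list[ReaderInput]] = []
    for r in range(spec.n_readers):
        seed_rng = _reader_rng(spec.rng_seed, r, repeat=10**6)  # per-reader seed stream
        picks = [
            _sample_seed_indices(seed_rng, len(cand), spec.n_repeats)
            for cand in lesion_candidates
        ]
        repeats = []
        for j in range(spec.n_repeats):
            coords = [tuple(int(v) for v in cand[p[j]]) for cand, p in zip(lesion_candidates, picks)]
            # a repeat may hit the same voxel for two tiny lesions; dedupe defensively
            coords = list(dict.fromkeys(coords))
            crescent = _crescent_for(phantom, spec, _reader_rng(spec.rng_seed, r, j))
            repeats.append(ReaderInput(seeds=SeedSet(coords), crescent=crescent))
        readers.append(repeats)
    return readers
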