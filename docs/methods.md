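# Methods

## The model

Amino-acid PET quantification in glioma normalises each voxel's SUV by the
mean SUV of a healthy contralateral background region ("CTRL VOI"),
producing the tumour-to-brain-ratio (TBR) map; the biological tumour
volume (BTV) is the connected supra-threshold region of that map grown
from a reader seed. `fetmirror` implements two ways of obtaining the
background mean:

**Mirror-image (MI), iterative.** The initial tumour segmentation BTV₀ is
grown on the SUV image at threshold 2.2 (a published cut-off for
recurrent glioma). At iteration *k*, CTRLₖ is the reflection of BTVₖ
across the mid-sagittal plane with tumour overlap and out-of-brain voxels
removed; its mean SUV *Sₖ* normalises the image, and BTVₖ₊₁ is regrown on
the TBR map at threshold 1.9. The loop stops when
|vol(BTVₖ₊₁) − vol(CTRLₖ)| ≤ 0.2 cm³. After convergence the reference is
rebuilt once against the final BTV and the reported background mean is
recomputed on it; the BTV is *not* regrown after this final exclusion
(stopping here keeps the reported pair self-consistent; regrowing would
re-open the loop). With multiple seeds (multifocal disease) the BTV and
its mirror are unions over lesions.

**Guided crescent-shape (gCS), single pass.** The reference is a
reader-drawn crescent VOI consumed as a mask file; its mean normalises
the image and the BTV is grown once at TBR ≥ 1.9. No iteration, no
overlap handling — the reference is solely the reader's drawing, which is
precisely why its placement variability propagates into the BTV.

### Assumptions

- Inputs are brain-extracted SUV volumes rigidly aligned so the
  left-right anatomical axis coincides with a grid axis; the mid-sagittal
  plane is the midplane of that axis (configurable, default axis 0).
  Whether the PET or a registered CT grid defines that axis is an
  upstream choice; the axis override covers both conventions.
- The brain is approximately left-right symmetric, so the mirror of a
  hemispheric lesion lands in contralateral tissue. Tumours heavily
  involving the midline violate this: the mirrored reference is then
  largely removed by overlap exclusion and the pipeline raises
  (`EmptyReferenceError`) rather than returning an approximate answer.

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `suv_threshold` | 2.2 | SUV | initial growth cut-off on the SUV image |
| `tbr_threshold` | 1.9 | TBR | growth cut-off on every TBR map |
| `volume_tolerance_cm3` | 0.2 | cm³ | convergence band |
| `max_iterations` | 50 | — | oscillation guard; exceeded ⇒ `converged=False`, never silent |
| `connectivity` | 26 | — | 3D neighbourhood for region growing |
| `exclude_hot_from_ctrl` | off | — | optionally drop supra-threshold TBR voxels from the final reference |

Threshold comparison is inclusive (≥): the common region-growing
convention, and it makes boundary voxels reproducible. 26-connectivity is
the default because PET uptake blobs are frequently only obliquely
contiguous at voxel scale; 6-connectivity is available. Convergence
compares the new BTV volume against the *previous* reference volume (the
natural reading of the stopping rule); the iteration trace records both
sequences so the alternative reading (BTVₖ vs BTVₖ₊₁) can be audited. A
two-cycle detector logs a warning when the BTV volume alternates between
two values.

The optional `exclude_hot_from_ctrl` flag additionally removes any
supra-threshold TBR voxel from the final reference region (so uptake
above background that is disconnected from the seeds cannot contaminate
it); it is off by default because the baseline method removes only BTV
overlap.

## Numerical and representational choices

- Coordinates are 0-based voxel indices; volumes are voxel count × voxel
  volume (mm³) / 1000, with spacing read from the NIfTI header and never
  assumed isotropic.
- Mirroring maps index *i* to *N−1−i* along the midline axis: an even
  axis reflects about the inter-voxel midplane, an odd axis fixes the
  central slab. The operation is an involution and preserves voxel count
  exactly, making results bit-reproducible.
- Region growing is computed as connected-component labelling of the
  supra-threshold set — mathematically identical to seeded flood fill
  (verified against a hand-coded BFS in the tests) and the source of the
  method's seed invariance: any seed inside a component selects the same
  component. Growing multiple seeds as a union of components is
  equivalent to pooled growth for thresholded connectivity.
- Masks are written as uint8 0/1 NIfTI, the de-facto segmentation
  interchange dialect; outputs carry the input image's affine unchanged.
- CoV uses the sample (n−1) standard deviation. With 6 repeats the n vs
  n−1 choice changes CoV by ~10 % relative, so it is pinned here.
- ICC(2,1) = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the
  two-way ANOVA mean squares; 95 % CIs use the McGraw–Wong F construction
  with Satterthwaite degrees of freedom (matching the pingouin reference
  implementation, which the tests cross-check to 1e-10 on the point
  estimate). Constant matrices are rejected as undefined rather than
  returning 0/0; exact column-wise agreement with between-target variance
  returns ICC 1 with a degenerate [1, 1] interval.
- Wilcoxon signed-rank and Mann–Whitney U comparisons are delegated to
  scipy.stats; all-zero paired differences (the common case when the MI
  method is compared with itself or variability is absent) are reported
  as `p_value: null` with a note instead of raising.

## The phantom generator

The phantom emulates the study conditions, not PET physics: an
ellipsoidal brain (default semi-axes 80/100/80 mm on a 90×108×90 grid at
2 mm spacing — head-sized) of uniform background SUV 1.0, spherical or
ellipsoidal lesions of SUV 3.0 (default radius 10 mm, centred 40 mm off
the midline), optional concentric rims of intermediate uptake, and
optional additive Gaussian noise clipped at zero. The defaults keep both
thresholds active: lesion SUV 3.0 clears the 2.2 SUV cut and has TBR 3.0
on a unit background; a rim between the two thresholds exercises the
difference between SUV-grown and TBR-grown volumes. The brain ellipsoid
is centred on the grid midpoint, so the brain mask is exactly
mirror-symmetric and mirrored references always land in valid tissue.

Simulated readers (default 7 readers × 6 repeats) sample seed voxels
uniformly inside the lesion (at or above the SUV threshold) and draw
crescents as contiguous background shells near the mirrored lesion
centroid, with jittered position and extent. A contamination fraction
swaps part of the crescent for elevated-uptake rim voxels, emulating
readers accidentally including hot tissue; the expected crescent mean is
then background + f·(rim − background). When the rim pool is smaller than
the requested swap, the crescent is shrunk so the mixture fraction is
preserved exactly.

**What passing tests show — and don't.** On these phantoms the MI
pipeline's zero intra-reader CoV and exact background recovery are
mathematical consequences of seed invariance and symmetry, and the tests
confirm the implementation realises them. Real brains add asymmetric
anatomy, spatially correlated noise, grey/white-matter contrast and
physiological uptake gradients; the phantom results therefore validate
the algorithmic mechanism (determinism, convergence, the direction of the
MI-vs-gCS variability contrast), not clinical magnitudes of CoV or ICC.

## Problem sizes

The bundled verification runs use the full-size default phantom for the
simulated reader study (42 pipeline runs) and a battery of 20 randomised
noisy phantoms (lesion radius 6–14 mm, noise sd 0.05) for the convergence
contract; unit tests use a compact 40×48×40 phantom. These sizes give
sub-minute runtimes while exercising every code path at realistic voxel
counts.

## Known limitations

- No partial-volume effects, smoothing, or hole-filling — the method
  defines none, and hard-edged phantom lesions make threshold behaviour
  exact rather than realistic.
- Midline-dominated tumours are out of the method's domain and fail
  loudly by design.
- The gCS drawing guidelines themselves (crescent shape spanning grey and
  white matter) are not encoded; the crescent is an input mask, and the
  simulator only mimics placement variability.
- ICC aggregation treats patients as targets and readers as raters on
  repeat means (the `icc_2_1` primitive accepts any complete matrix if a
  different aggregation is wanted).
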