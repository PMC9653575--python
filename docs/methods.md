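# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `petmtv`. It states no empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and geometry

Volumes live on axis-aligned grids indexed `[x, y, z]` (x left→right,
y anterior→posterior, z inferior→superior), world coordinates in mm at
voxel centres, voxel volume `sx·sy·sz/1000` cm³. CT is in Hounsfield
units, PET in body-weight SUV (`SUV = C·weight/dose`, dose decay-corrected
to scan start; whether the source data used a different SUV convention is
an input-side responsibility). CT-grid masks move to the PET grid by
nearest-neighbour lookup in world coordinates — masks encode set
membership, so no partial-volume interpolation is wanted. NIfTI is the
interchange format (organ label map: 1 brain, 2 heart, 3 kidney-left,
4 kidney-right, 5 bladder); DICOM series input is a thin optional wrapper
over SimpleITK's reader.

## Synthetic phantoms

The generator emulates the geometry that drives each pipeline stage, not
anatomy: ellipsoidal organs with typical FDG uptake (background soft
tissue SUV 1; brain 7, myocardium 5, kidneys 6, bladder 15), spherical
lesions of known voxelized volume (avid lymphoma ≈ SUV 8), optional
ureter-like capsules (SUV 8, radius 3 mm) descending medially from the
kidneys to the bladder dome, optional Gaussian PSF blur (FWHM in mm) and
additive Gaussian SUV noise. CT values are distinct noise-free constants
per structure (0/15/25/35/45/55 HU) so the organ classes are well posed.
Ground-truth masks are voxelized **before** blur and noise: blur models
the scanner response, not anatomy, so truth stays unambiguous. The default
grid is 96×96×160 at 4 mm isotropic (384×384×640 mm) so a full pipeline
run takes seconds.

Cohort simulation draws per-case lesion count (1–5), radius (8–20 mm) and
uptake (SUV 6–12), jitters organ centres by ±4 mm, and places lesions by
rejection sampling away from organs (10 mm clearance), other lesions, and
the kidney–bladder urinary corridor. The corridor exclusion is a modelling
choice made up front: the method by construction discards uptake in the
urinary zone, and the nodal stations this cohort emulates lie outside the
urinary tract; a lesion deliberately placed inside the corridor is the
documented failure mode of the zone rule, exercised separately in the
hand-trace tests.

What passing on phantoms does **not** show: robustness to real-CT contrast
between organs and surrounding soft tissue, misregistration, respiratory
motion, heterogeneous lesion uptake, or scanner-dependent reconstruction.
Published segmentation and concordance figures on trial data are
surrogate targets here, reached on an easier synthetic task.

## Organ segmentation

A 2-D dilated residual U-Net labels each axial CT slice with 5 classes:
background plus the four avid target structures (brain, heart, kidneys,
bladder). The two kidneys are a single network class: they are identical
in intensity and shape and differ only by side, so teaching a
convolutional network two position-coded copies of the same organ is both
unnecessary and fragile — left/right attribution is instead a geometric
postprocess on the predicted kidney components (below). Five encoder and five decoder cascades of
residual blocks (two 3×3 convolutions each, batch norm, projected
shortcut when widths change); 2×2 max-pool downsampling, ×2 bilinear
upsampling, skip concatenation; the fifth decoder cascade runs at full
resolution before a 1×1 classifier; the input slice is concatenated onto
the final feature map, a shortcut from input to output that matters at
desk-scale widths — with only four full-resolution channels, training can
otherwise fall into a sticky state where one intensity-coded tissue
collapses onto another in feature space and its class never recovers.
Per-level dilation defaults to 1 with
a dilated-bottleneck preset (rates 2, 4) available — the architecture
family is dilation-parameterized but no specific rates are normative.
Input sizes must be divisible by 16.

Preprocessing shifts CT to nonnegative values, clips to 1–99% of the
intensity *range* (a percentile variant is available behind `mode=`), and
Z-score-standardizes per volume; the literal range reading is the default
because the clipping rule is stated in terms of the maximum.

Training: cross-entropy + soft-Dice (weight 0.5/0.5; batch-global sums,
smoothing 1.0), Adam with weight decay 1e-4, LR 3e-4 stepped to 3e-6 from
epoch 60 on (an absolute epoch: shorter desk-scale budgets therefore
train at the full rate throughout), affine augmentation (rotation ±10°,
translation ±8 mm, scale 0.9–1.1, horizontal flip p=0.5 with left/right
kidney labels exchanged so each label keeps meaning "the kidney on that
side"), volumes split 5:1:4 into train/val/test. The Dice term averages
only over the foreground classes present in the batch: for an absent
class its gradient is a uniform push toward zero probability, orders of
magnitude stronger per pixel than cross-entropy, and including absent
classes makes survival of rare classes a seed-dependent race. Training
slices are sampled class-stratified (round-robin over the structures in
each volume) so that the kidneys and bladder, which occupy narrow
z-ranges, are represented every epoch. The engine is float32 numpy with
hand-written backward passes (verified against finite differences in the
test suite) and is bit-reproducible under a fixed seed on a given
machine.

Desk-scale choices: the network defaults used by the acceptance surrogate
are narrow (widths 4, 8, 16, 32, 32 — published per-level widths are not
normative), training samples 16 slices per volume per epoch (¾ drawn from
organ-bearing slices) in batches of 4 at a fixed central 64×64 in-plane
window that covers the whole organ field with margin. The fixed window —
rather than random crops — keeps training and inference geometry
identical; inference uses the same window and fills background outside
it, which assumes the organs lie in the central field of view (true for
the phantoms; for other data disable with `crop_size=None`). 30 epochs
≈ 3000 Adam steps suffice on the synthetic task.

Inference is slice-wise with 3-D restacking; argmax makes organ masks
disjoint by construction. Two postprocessing rules make the masks usable
downstream: connected components of the kidney class are
assigned to left/right by x-centroid (threshold midway between the two
largest components; grid midline if only one), and only the largest
26-connected component of each organ is kept — one brain, one heart, one
bladder, one kidney per side is an anatomical constraint, and a stray
false-positive island would otherwise carve a hole into the MTV analysis
space and, worse, let the contour-transfer stage absorb a genuine lesion
near it.

Fine-tuning re-randomizes the 1×1 classifier and trains either the final
layer only or all layers (`trainable_scope`); the published description
is ambiguous on this point, so both scopes are exposed.

## Contour transfer

Per organ: resample the CT mask to the PET grid; seeds = mask eroded by
4 mm (falling back to the whole mask for thin organs); grow from
supra-threshold seeds over 26-connected supra-threshold voxels, bounded
by the mask dilated by 12 mm; if no seed exceeds the threshold, keep the
resampled contour and warn. The inclusion threshold is
`min(0.5 × P95(SUV inside the contour), 2 × background)` where background
is the median SUV outside all contours. The background floor is a
deliberate extension of the fraction-of-peak rule: for a hot organ
(bladder ≈ SUV 15 on background 1) half the robust peak still sits far
above the MTV threshold, which would leave a point-spread halo outside
the adapted contour to be mistaken for tumor; following spill down to
~2× background absorbs the whole PET presentation of the organ while
cold surroundings stay out. Overlapping adapted masks are disjointified
per voxel toward the organ in whose uptake distribution the voxel ranks
highest. An optional fast-marching refinement (SimpleITK) propagates a
front from the seeds with speed ∝ SUV and accepts arrival times within
the margin; it subsumes the role of an active-contour pass and is off by
default. The 12 mm margin acts only as a growth bound, not as an extra
exclusion ring.

## Trapezoid urinary exclusion zone

From the superior pole of the kidneys (most superior kidney voxel) down
to the bladder's central cross-sectional plane (rounded z-centroid of the
bladder mask; nearest occupied plane if that plane is empty). Top base:
x between the two kidney x-centroids, y over the combined kidney extent;
bottom base: the bladder's x/y bounding extents in its central plane;
per-slice rectangles interpolate the four bounds linearly in z, with
bounds rounded to the nearest voxel. Degenerate geometry (bladder plane
above the kidneys) raises a diagnostic error.

## The iterative MTV loop

Analysis space = whole grid (optionally voxels above a body threshold)
minus the five adapted organ masks. Each iteration: global SUVmax over
the current space (ties broken to the smallest C-order linear index);
threshold = 0.41 × SUVmax; supra-threshold is inclusive (≥); connected
components at 26-connectivity (configurable 6/18/26 — the contiguity
neighbourhood is not normative); candidates are clusters strictly
> 1 cm³; candidates strictly < 2 cm³ are screened as too small; a
candidate "falls in" the zone when more than 50% of its voxels lie inside
the zone mask (`majority` rule; `any_overlap` and `centroid` variants are
provided). If the cluster containing the SUVmax voxel is retained the
loop stops; otherwise that cluster's voxels leave the analysis space and
the loop repeats — a cluster that fails even the 1 cm³ candidacy cut is
treated as screened out, which is required for termination. Each removal
strictly shrinks the space, so thresholds decrease and the loop
terminates (a guard of 100 iterations flags degenerate inputs). The two
size constants are kept as independent parameters; their interplay
(candidates > 1 cm³, lesions ≥ 2 cm³) is preserved as published without
interpretation.

Reported MTV = Σ retained volumes (exactly voxel count × voxel volume);
reported SUVmax = maximum within retained lesions, with the global
maximum logged alongside — which of the two the published tables report
is not stated, and the retained-lesion maximum is the defensible reading
for a lesion-level biomarker. An optional per-lesion 41% re-thresholding
post-pass (the readers' convention) exists conceptually in the semi-
automatic workflow but is out of scope here.

## Agreement statistics

Pearson r (two-sided t test) via scipy; ICC via pingouin's
`intraclass_corr`, defaulting to the two-way random, absolute-agreement,
single-measurement form ICC(2,1) — the standard for method comparison —
with the variant exposed; F-based 95% CI (collapsed to the point estimate
when the mean squares degenerate at perfect agreement). Bland–Altman:
mean difference ± 1.96 × sample SD of differences. RMSE = √mean(d²) with
d = reference − method; positive bias = mean of positive differences,
negative bias = mean magnitude of negative ones (zero when none) — the
published bias numbers come without a formula, and this is one consistent
reading, documented as such. Sample (n−1) SDs everywhere; CV% =
100·SD/mean. Where two readers form the reference, their elementwise mean
is used.

## Numerical and reproducibility notes

All randomness flows through explicit `numpy.random.Generator` seeds;
phantom generation, training and the pipeline are bit-reproducible per
machine. The CV self-consistency check carries ~1e-3 slack because its
inputs are printed to three decimals. Gradient correctness is tested by
finite differences (in float64 for composed blocks, where float32 ReLU
kink-crossing makes naive FD noisy). Empty analysis spaces yield MTV 0
rather than errors; empty organ masks yield empty transferred masks; a
missing kidney/bladder disables the zone with a warning rather than
failing the case.

## Known limitations

* Phantom realism is deliberately minimal (see above); Dice and
  concordance on phantoms overstate what the same configuration would
  achieve on clinical CTs.
* The fixed 64×64 analysis window assumes centred anatomy.
* The loop inherits the method's blind spot: a genuine lesion mostly
  inside the urinary corridor is screened out by design.
* Slice-wise 2-D inference has no through-plane context; the
  keep-largest-component rule would discard a true second focal
  component of an organ (e.g. transplanted kidney).
* When every avid focus is screened out, thresholds fall toward
  background; the iteration guard catches the pathological limit, but on
  lesion-free scans the method reports the largest warm structure above
  41% of whatever maximum remains — lesion-free inputs should be handled
  upstream.
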