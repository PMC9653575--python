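# petmtv

Fully automated computation of **metabolic tumor volume (MTV)** and
**SUVmax** from whole-body FDG-PET/CT, aimed at quantitative imaging in
lymphoma (DLBCL), where total MTV is a validated prognostic biomarker but
is tedious to measure with semiautomatic tools.

The pipeline mirrors how a nuclear-medicine reader works through a scan:

1. **Organ segmentation (CT).** A 2-D dilated residual U-Net labels the
   physiologically FDG-avid structures — brain, heart, both kidneys,
   bladder — on axial CT slices (5 encoder and 5 decoder cascades of
   residual blocks, 3×3 kernels, max-pool down / bilinear up, batch norm,
   skip connections; trained with a cross-entropy + soft-Dice loss, Adam,
   weight decay 1e-4, LR 3e-4 stepped to 3e-6 after 60% of the epochs).
   The network runs on a compact numpy engine with hand-written backprop,
   so training and inference need only a CPU.
2. **Contour transfer (CT → PET).** Each CT contour is adapted to its PET
   presentation: resample to the PET grid, erode to seeds, region-grow
   over 26-connected voxels above an uptake threshold, bounded by a
   12 mm dilation margin (optional fast-marching refinement).
3. **Trapezoid urinary exclusion zone.** A frustum between the kidneys'
   superior poles and the bladder's central plane (top base between the
   kidney midlines, bottom base at the bladder's borders) catches ureter
   uptake and stray urinary activity.
4. **Iterative MTV loop.** Inside the body volume minus the organs:
   threshold at **41% of SUVmax**, cluster contiguous supra-threshold
   voxels (26-connectivity), keep clusters **> 1 cm³** as candidates,
   screen out candidates **< 2 cm³** or falling in the zone; if the
   cluster holding the SUVmax voxel was screened out, remove it from the
   analysis space and repeat with the next SUVmax. MTV is the summed
   volume of the retained lesions.

Because real trial images and reader annotations are not redistributable,
the package ships a **synthetic phantom generator** (ellipsoid organs,
spherical lesions of known voxelized volume, optional ureter streaks, PSF
blur, noise) so every stage — including network training — is testable
end-to-end from nothing, plus the **method-agreement statistics** used for
validation: Pearson r, absolute-agreement ICC(2,1) with 95% CI,
Bland–Altman bias and limits of agreement, RMSE with signed biases, and
coefficients of variation.

## Worked example

```python
from petmtv import (default_phantom_spec, generate_phantom, compute_mtv,
                    UreterSpec)

spec = default_phantom_spec(ureter=UreterSpec(), blur_fwhm_mm=6.0,
                            noise_sigma_suv=0.1, seed=3)
case = generate_phantom(spec)                 # paired CT/PET + ground truth

from petmtv import transfer_contours
organs_pet = transfer_contours(case.organs, case.pet)
result = compute_mtv(case.pet, organs_pet)
print(f"MTV  = {result.mtv_cm3:.2f} cm3 (truth {case.truth_mtv_cm3:.2f})")
print(f"SUVmax = {result.suvmax:.2f}, iterations = {result.n_iterations}")
```

prints

```
MTV  = 23.17 cm3 (truth 23.10)
SUVmax = 8.24, iterations = 1
```

i.e. on a blurred, noisy phantom with two avid lesions (SUV 8 on
background 1) and ureter streaks, the automated loop recovers the true
tumor burden within 0.3% in a single iteration; the ureter uptake is
discarded by the trapezoid zone, and the reported SUVmax is the noisy
lesion peak. The same flow runs from the shell:

```bash
petmtv simulate --n 5 --seed 1 --out cases/
petmtv train    --data cases/ --epochs 30 --out model.npz
petmtv run      --ct cases/case_000_ct.nii.gz --pet cases/case_000_pet.nii.gz \
                --model model.npz --out report.json
petmtv agree    --csv paired_mtv.csv
```

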