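# lvmotion

A two-parameter empirical model of left-ventricle (LV) short-axis wall
motion, with the full tagged-MRI-style fitting pipeline around it:

* **transform** — the analytic motion model: an isotropic radial
  contraction (parameter `alpha`, mm; radial displacement `alpha²/r`)
  composed with a radially non-uniform rotation (parameter `beta`, mm;
  rotation angle `beta/r`, positive = clockwise viewed head-to-toe),
  plus the closed-form inverse.
* **mesh** — simulated tag-grid construction (7 mm cells by default),
  annulus masking, model deformation, and binary rasterization.
* **preprocess** — intensity normalization, tag-line binarization
  (local-mean thresholding robust to tag fading), LV geometry
  estimation (automatic two-circle fit or manual radii), cropping, and
  PNG/TIFF/NIfTI series I/O with a YAML/JSON metadata sidecar.
* **fit** — the figure-of-merit `F(alpha, beta, t)` (mean squared
  model/image difference over mesh pixels, 0 = perfect match, 1 =
  complete mismatch) and an exhaustive coarse-to-fine grid scan of the
  normalized `alpha/r_epi × beta/r_epi` plane; per-frame fits are
  assembled into normalized temporal profiles and can be aggregated
  across subjects (mean ± SD).
* **phantom** — a synthetic tagged-MRI generator: an annular LV wall
  with a deforming tag grid rendered by inverse mapping (exactly
  model-consistent), tag fading, additive noise, and full ground truth
  for parameter-recovery validation.
* **biomarkers** — derived markers: endocardial radius change
  `alpha²/r_endo`, cavity-area reduction (exact and the `2·pi·alpha²`
  approximation), and apex-base twist.

## CLI

```sh
# render a synthetic series (frames + ground-truth CSV + sidecar)
lvmotion simulate --out out/series --level apex --seed 1 --noise-sigma 0.02

# fit a series (PNG/TIFF directory or NIfTI + sidecar) -> profile CSV
lvmotion fit out/series --out out/profile.csv

# derived markers (optionally with apex/base profiles for twist)
lvmotion report --profile out/profile.csv --r-endo 15 --out out/markers.json

# end-to-end demo over all three slice levels
lvmotion demo --out out/demo --seed 0
```

CSV/JSON column meanings are documented in `src/lvmotion/schema.json`.

## Conventions and caveats

* Physical coordinates are LV-centered millimetres (x right, y up);
  array indices are `(row, col)` with `pixel_spacing = (row_mm,
  col_mm)`. The image-frame chirality flip is confined to the mesh
  rasterizer's coordinate mapping.
* Frame 0 of a series is end-diastole and is fixed at
  `(alpha, beta) = (0, 0)`; every later frame is fitted independently
  for the *total* deformation since end-diastole.
* The model describes global motion only and the rotation-angle law
  `beta/r` yields larger angles at smaller radii — see the `transform`
  module docstring for the discussion of this empirical choice.
* The grid-scan cost is pixel-quantized; at very small deformations
  (sub-pixel displacements) recovered parameters are accurate to about
  two coarse grid steps. `FitConfig(bilinear=True)` enables sub-pixel
  image sampling, which tightens small-deformation recovery and is
  several times faster.
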