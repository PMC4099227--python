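# Methods

## Problem and pipeline

Lytic lesions of bone from multiple myeloma (MM) and from osteolytic
metastases (OL) both present as radiolucent defects on plain radiographs.
The pipeline quantifies a manually outlined rectangular ROI on a 12-bit
digitized radiograph with three first-order gray-level statistics and
asks how well each statistic separates the two diseases, stratified by
bone class (flat bones — skull, ribs, sternum, pelvis — versus nonflat
trabecular/cortical bones), giving four strata: MM1/OL1 (nonflat) and
MM2/OL2 (flat).

Steps per ROI: read image → extract ROI → anisotropic diffusion →
MGL/SDGL/CVGL; then per bone class: descriptives, two-sample *t* test,
and nonparametric ROC/AUC with the metastasis group as positive class.

## Image model and conventions

* Gray levels are integers in [0, 4095] (12 bits), stored unscaled in
  16-bit single-channel TIFF or PNG. A 16-bit container whose values all
  fit in 12 bits is treated as 12-bit. (Digitized film at 12 bits has
  4096 levels, 0–4095; a nominal "0–4096" range sometimes quoted for such
  scanners is off by one and is normalized here to 0–4095.)
* ROIs are 0-based, half-open rectangles, row-major (y = row, x = col).
  The study default is width 40 × height 50 (2000 pixels); any rectangle
  is accepted.
* DICOM is out of scope; inputs are film digitizations converted to
  TIFF/PNG.

## Anisotropic diffusion

Classic Perona–Malik explicit scheme on the 4-neighborhood with zero-flux
boundaries and Jacobi updates:

    u_new(p) = u(p) + λ Σ_{q∈N(p)} g(u(q) − u(p)) · (u(q) − u(p))

with conductance `exp(−(d/K)²)` (default) or `1/(1+(d/K)²)`. Defaults:
10 iterations, K = 30 native gray units, λ = 0.25 (the 4-neighbor
stability limit; λ = 0 is allowed as a degenerate identity step). The
scheme conserves the pixel sum exactly, obeys a discrete maximum
principle, and is monotone in grid variance; all three are enforced by
property tests, and the update is cross-checked against an independent
scalar-loop implementation.

No published parameter set exists for the source workflow (the filter is
specified only by citation), so exact pixel-level replication of the
original filtered images is not attempted; the defaults are exposed in
the config (`diffusion.*`) and the first-order features depend only
weakly on them. Filtering runs in floating point and features are
computed on the unquantized filtered grid — requantization would add an
arbitrary rounding rule. A config switch disables filtering entirely.

## Gray-level features

MGL is the arithmetic mean of the ROI values, SDGL the sample (n−1)
standard deviation, CVGL = (SDGL/MGL)·100 (percent). With 2000-pixel
ROIs the n vs n−1 choice moves SDGL by <0.03%; the denominator is
switchable (`sd_denominator = n`). CVGL is undefined for MGL = 0 and
raises a dedicated error. The histogram (default 4096 equal-width bins
over the full range) is a reporting artifact; features are computed from
the pixel values directly.

## Statistics

* Group comparison: two-sided independent two-sample *t* test; pooled
  (Student) variance by default, Welch optional. A paired test is not
  meaningful for these structurally unpaired groups of unequal size.
  No multiple-testing adjustment is applied; raw P values are reported.
* Diagnostic ability: tie-corrected Mann–Whitney estimator of the AUC,
  computed via midranks (identical to pairwise counting with half credit
  for ties; verified against brute-force enumeration). Standard error by
  Hanley–McNeil; the test of AUC = 0.5 uses the Hanley–McNeil variance
  evaluated under the null (Q₁ = Q₂ = 1/3), matching the classical
  asymptotic nonparametric test. A DeLong variance is available as an
  alternative SE but is not the default.
* Positive class: osteolytic metastases, scores oriented as the raw
  feature value. This is the only orientation jointly consistent with
  the calibrated group means and the published AUC table (flat-bone
  MGL/SDGL AUC > 0.5 with OL means higher; nonflat MGL AUC < 0.5).
* ROC curves are emitted at every distinct threshold with (0,0) and
  (1,1) anchors; the trapezoidal area equals the Mann–Whitney estimator
  to 1e−12 (tested).

## Synthetic-data generator

The generator defines the study conditions; it is calibrated once to the
published per-stratum statistics and group sizes (MM1: 31, OL1: 35,
MM2: 36, OL2: 41) hard-coded in `study_presets()`.

* **Case level.** MGL ~ N(μ_MGL, σ_MGL) and SDGL ~ N(μ_SDGL, σ_SDGL),
  drawn independently — no correlation information is published. SDGL
  draws are floored at 1 gray level (unless the configuration is
  deliberately degenerate with σ_SDGL = 0). CVGL is always derived per
  case as SDGL/MGL·100, matching its definition; as a ratio statistic
  its group mean only approximately matches the published CVGL means
  (Jensen's inequality), so the published CVGL rows are used as a
  simulation target only where CVGL itself is the score, never as an
  extra calibration constraint. The published min/max columns are kept
  as sanity ranges, not truncation bounds (truncation is available via
  `truncate=True`); normality is the simplest model consistent with the
  printed moments, and the binormal cross-check validates it.
* **Pixel level.** ROI pixels are i.i.d. N(MGL, SDGL), rounded and
  clipped to [0, 4095]. Rounding adds variance 1/12 gray² and clipping
  is negligible at the calibrated scale, so features recover the case
  parameters to within sampling error (SE_MGL = SDGL/√2000 ≈ 5.5).
* **Phantom scenes.** A full radiograph phantom is a smooth horizontal
  background gradient, a brighter horizontal bone band, and a darker
  elliptical lytic lesion (lytic = radiolucent) whose interior is the
  pixel-level model above; non-lesion pixels get additive N(0, noise_sd)
  noise. The ground-truth ROI returned with each scene is the
  study-default 40×50 rectangle centered on the lesion and verified to
  lie inside the ellipse, so ROI features estimate the lesion
  parameters; an ellipse *bounding box* would mix ≈21% bone-band pixels
  into the ROI and bias every feature. For unusually bright cases the
  band level is raised automatically to keep the lesion darker than the
  band.
* **Seeding.** One master seed; every stream is derived by stable
  hashing of (seed, stratum label, case index) via `SeedSequence`, so
  generation is a pure function of (parameters, seed), independent of
  call order, and all derived seeds stay below 2³¹.

What the phantoms do **not** emulate: X-ray physics (beam hardening,
scatter, screen-film response), anatomy, spatially correlated film
grain, or manual ROI placement variability. Passing tests therefore
demonstrate that the *estimators and pipeline plumbing* are correct and
calibrated, not that the gray-level parameters separate the diseases on
real radiographs.

## Recovery checks and problem sizes

* Feature-level Monte Carlo: 2000 replicate studies per target quantity
  (seconds at these group sizes); the mean empirical AUC is compared
  with the binormal closed form Φ(Δμ/√(σ₊²+σ₋²)) and with the published
  table. Finite-sample empirical AUC is an unbiased U-statistic, so the
  Monte Carlo mean matches the closed form at any group size.
* Parameter recovery: 200 replicate case-level studies per stratum;
  group means of MGL and SDGL are tested for bias (one-sample *t*,
  α = 0.01). Pixel-level recovery is tested on rendered ROIs with the
  filter **off**: on i.i.d.-noise phantoms the diffusion filter
  attenuates exactly the quantity SDGL measures, so unbiasedness is a
  property of the unfiltered features; with the filter on, MGL is still
  conserved (tested) while SDGL shrinks slightly.
* The demonstration cohort (analysis/) renders 143 phantom scenes of
  128×128 pixels and runs the full pipeline in a few seconds.

## Known limitations

* The CVGL null behaviour on flat bones (published AUC 0.483) emerges
  from the calibrated marginals (simulation gives ≈0.51); without the
  unpublished MGL–SDGL case-level correlation, closer agreement is not
  identifiable from the published summaries.
* The filter parameters of the original workflow are unknown; results
  are reported for the documented defaults.
* Report CSVs are byte-reproducible across reruns; the run log contains
  a config hash rather than a wall-clock timestamp for the same reason
  (the in-memory report carries a timestamp in its provenance).
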