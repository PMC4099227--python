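# lyticgray

Quantitative characterization of lytic bone lesions on digitized skeletal
radiographs, for differentiating **multiple myeloma (MM)** from
**osteolytic metastases (OL)**.

Both diseases produce radiolucent ("punched out") bone defects that are
hard to tell apart on plain film. This package implements a first-order
gray-level workflow over a manually placed region of interest (ROI,
40×50 pixels by default) on a 12-bit digitized radiograph:

1. **ROI extraction** from a 16-bit TIFF/PNG container (values 0–4095);
2. **edge-preserving denoising** by Perona–Malik anisotropic diffusion,
   `u ← u + λ Σ_q g(∇u)·∇u` with conductance `g(d) = exp(−(d/K)²)` or
   `1/(1+(d/K)²)`;
3. **gray-level histogram features** per ROI:
   * MGL — mean gray level,
   * SDGL — standard deviation of gray level (sample, n−1),
   * CVGL = (SDGL/MGL)·100;
4. **group statistics** stratified by bone class (flat vs nonflat bone):
   descriptives, two-sample *t* tests, and nonparametric diagnostic
   ability as the tie-corrected Mann–Whitney AUC
   `AUC = [#(x_OL > x_MM) + ½·#(ties)] / (n_OL·n_MM)`
   with Hanley–McNeil standard errors and a normal test of AUC = 0.5.

Because the original radiographs are not distributable, the package ships
a **synthetic-study generator** calibrated to the published per-stratum
statistics of the source study (four strata: MM1/OL1 nonflat, MM2/OL2
flat; n = 31/35/36/41). It draws per-case (MGL, SDGL) from normal models,
renders pixel-level phantom radiographs (background gradient, bright bone
band, dark elliptical lytic lesion), and lets the entire pipeline run and
be validated end to end. For normal models the expected AUC has the
binormal closed form `Φ(Δμ/√(σ₊²+σ₋²))`, which serves as the independent
oracle for the Monte Carlo checks.

## Worked example

```sh
python analysis/01_simulate_study.py     # 143 phantom radiographs + manifest
python analysis/02_run_study.py          # full pipeline -> results/report/
python analysis/03_diagnostic_performance.py
```

The pipeline report on the seed-1 synthetic cohort prints, among others:

```
parameter bone_class   auc    se  p_value  n_pos  n_neg
      mgl       flat 0.730 0.057    0.001     41     36
     sdgl       flat 0.869 0.041    0.000     41     36
     cvgl       flat 0.524 0.066    0.721     41     36
```

i.e. on flat bones SDGL separates the two diseases best, MGL well, and
CVGL not at all — the OL lesions are brighter and more heterogeneous than
the purely lytic MM lesions, but their *relative* dispersion is the same.
The Monte Carlo recovery table (2000 replicate studies) confirms the
estimator is calibrated against the closed form:

```
bone_class parameter  mc_mean_auc  binormal_auc
      flat       mgl       0.7472        0.7484
      flat      sdgl       0.8790        0.8785
   nonflat       mgl       0.4305        0.4292
```

Equivalent CLI entry points: `lyticgray simulate --preset study --seed 1
--out DIR`, `lyticgray run --config FILE`, and
`lyticgray features IMAGE --roi x0,y0,w,h`.

## Layout

| path | contents |
| --- | --- |
| `src/lyticgray/` | library: imaging, diffusion, features, stats, synthetic, pipeline, CLI |
| `analysis/` | numbered drivers reproducing the full study on synthetic data |
| `scripts/acceptance.py` | headline-number recomputation |
| `docs/methods.md` | models, parameters, numerical choices, limitations |
| `tests/` | unit + property + acceptance suites |
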