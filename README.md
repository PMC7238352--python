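# birads-cad

A computer-aided diagnosis (CAD) pipeline for classifying mammographic
masses into the four BI-RADS assessment categories B-2 (benign), B-3
(probably benign), B-4 (suspicious) and B-5 (highly suggestive of
malignancy). Radiologists assign these categories from a mass's shape,
margin and density descriptors together with its size and the patient's
age; this package implements that reading quantitatively, end to end:

1. **Preprocessing** — square ROI cropping around the reported lesion
   center and classical histogram equalization
   (`v -> round(255 · CDF(v))`).
2. **Segmentation** — seeded region growing from the ROI center pixel:
   the mask at threshold *t* is the 8-connected component of pixels with
   grey level ≥ *t*. Candidates are grown at thresholds spanning the
   ROI's grey range and one is selected automatically (equivalent-circle
   radius closest to the reported lesion radius) or interactively, in
   place of the expert radiologist of the original protocol.
3. **Feature extraction** — 130 handcrafted BI-RADS features per mass:
   - ids 1–9, *shape*: boundary continuity, curvature, irregularity
     (turning-angle count), convex-hull difference area, and
     mean/variance/skewness/kurtosis/entropy of the variation function
     (Feret diameter over 180 directions);
   - ids 10–11, *additional*: mass size in mm² and patient age in years;
   - ids 12–32, *margin*: 32 radial intensity waveforms of length 64
     (θ = π/16 apart) reduced to edge-probability vectors, whose
     kurtosis, entropy and index-of-maximum are summarized by 7
     statistics across waveforms (3 × 7 = 21);
   - ids 33–130, *density*: the 14 Haralick descriptors of grey-level
     co-occurrence matrices at 8 angles and all displacements
     d ∈ 1..⌊L/2⌋, angle-averaged per distance and summarized by the
     same 7 statistics (14 × 7 = 98).
4. **Normalization** — per-feature min–max scaling
   `d_norm = (d − d_min)/(d_max − d_min)` fitted on the training split.
5. **Feature selection** — a modified genetic algorithm over
   integer-id chromosomes: a chromosome of length *L* is a set of *L*
   distinct feature ids; reproduction uses elitism (best 2), roulette
   selection `P(c_i) = f(c_i)/Σf(c_j)`, (L−1)-point alternating
   crossover with `P_c = 1`, and duplicate-repairing mutation with
   `P_m = 0.01`. The GA runs once per subset size; the sweep over all
   sizes yields per-size bests and a global optimum.
6. **Classification** — a one-hidden-layer back-propagation network
   (logistic hidden units, softmax output) with the sizing rule
   `H = ⌊O + 0.75·I⌋`, `H < 2·I` (O = 4 classes), trained on a
   stratified 60/40 split; the subset fitness used by the GA is
   cross-validated accuracy carved from the training split only.
7. **Evaluation** — four-class confusion matrix, accuracy, per-class
   sensitivity/specificity, and micro-averaged PPV, NPV and Matthews
   correlation coefficient.

No mammography database is needed: the `synthfix` module generates
lesion phantoms with controllable boundary irregularity, margin blur and
interior contrast (with ground-truth masks), and labeled synthetic
feature tables for exercising the selection and classification stages.

## Worked example

```python
from birads_cad.synthfix import PhantomSpec, make_phantom
from birads_cad.pipeline import segment_case, extract_case

roi, truth, meta = make_phantom(PhantomSpec(category="B4", seed=8))
mask = segment_case(roi, meta["approx_radius_px"])
fv = extract_case(roi, mask, age_years=61.0)
print(f"segmented area: {mask.area_px} px (truth {truth.area_px} px)")
for name in ("irregularity", "difference_area", "mass_size",
             "margin_entropy_mean", "contrast_mean"):
    print(f"{name:22s} {fv.by_name(name):8.3f}")
```

prints

```
segmented area: 1143 px (truth 1264 px)
irregularity             11.000
difference_area          52.000
mass_size                 2.858
margin_entropy_mean       4.816
contrast_mean           746.538
```

The segmenter recovers most of the irregular B-4 phantom (1143 of
1264 px). Its boundary changes direction 11 times (a disc phantom gives
0), its convex hull exceeds the mass by 52 px, the mass covers
2.86 mm² at 0.05 mm pixel spacing, and the blurred margin spreads the
edge evidence to 4.8 bits of entropy (a sharp circumscribed margin is
near 1–2 bits).

A full run — phantom cohort, segmentation, extraction, GA selection and
classifier evaluation — is one call:

```python
from birads_cad.pipeline import RunConfig, run_all

report = run_all(RunConfig(seed=2, n_cases=120, ga_lmax=3))
print(report["selected_feature_ids"], report["metrics"]["accuracy_pct"])
```

The same stages are scriptable from the shell (`birads-cad segment`,
`extract`, `synth`, `select`, `evaluate`, `run --config run.yaml`).

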