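# ctsma — CT-based subchondral trabecular microstructure analysis

Quantitative trabecular biomarkers — bone volume fraction (BV/TV), trabecular
thickness (Tb.Th), separation (Tb.Sp) and number (Tb.N) — predict knee
osteoarthritis onset and progression, but computing them reliably requires
high-resolution MRI (e.g. balanced-FFE at ~0.23 mm in-plane). Routine
clinical CT is cheap and ubiquitous, yet its ~1 mm voxels smear individual
trabeculae into partial-volume soup. `ctsma` implements a cross-modal
pipeline that *trains* with MR and *deploys* on CT alone:

1. **Registration + synthesis.** A global rigid transform `Rg` maximizing
   mutual information `MI(A,B) = Σ p_AB log(p_AB / p_A p_B)` coarsely aligns
   MR to CT; a structure-preserving synthesis GAN (two generators, two patch
   discriminators, loss `L_SPS = L_GAN^CT + L_GAN^MR + λ_cyc L_cyc + λ_MI L_MI`
   with λ_cyc = 1.0, λ_MI = 0.5) maps MR to a CT-like appearance; and
   per-bone rigid refinements `Rf`, `Rt` handle the independent femur/tibia
   motion of an articulated joint, composited as
   `I_rr = Rf(I)·M_f + Rt(I)·M_t`.
2. **Distillation regression.** A 3D teacher CNN regresses
   y = (BV/TV, Tb.Th, Tb.Sp, Tb.N) from 48×48×16 MR patches; a student CNN
   regresses the same targets from the co-located 12³ CT patch under
   `L_reg^S + L_d`, where
   `L_d = w₁‖ŷ_S − ŷ_T‖² + Σ_j w₂ⱼ‖M_S^j − M_T^j‖₁`
   distills the frozen teacher at the prediction and feature levels.
   Inference uses the CT student only.
3. **Patient-level aggregation.** Patch predictions with sinusoidal
   positional encodings of their centres form tokens `u_i = [ŷ_i; φ(c_i)]`,
   processed by a two-layer transformer encoder, average-pooled, and read
   out by a softmax disease-grade classifier and a continuous severity-score
   head.

Because no clinical cohort ships with the package, a first-class synthetic
phantom module provides the ground truth everything is tested against:
thresholded-Gaussian-random-field trabecular microstructure at MR
resolution, a physically degraded CT counterpart (blur → downsample →
intensity remap → noise), two bone compartments with independent known
rigid motions, exact landmarks, and cohorts whose regional morphometry
shifts with a latent 3-class disease grade plus a continuous severity
score. Morphometry itself (maximal-inscribed-sphere local thickness on the
anisotropic physical grid, plate-model Tb.N = BV/TV / Tb.Th) is validated
against analytic slab/ball phantoms and brute-force sphere search.

Audience: researchers in quantitative musculoskeletal imaging who want a
tested, CPU-only reference implementation of synthesis-guided cross-modal
registration, distillation-based biomarker regression, and set-transformer
aggregation — or any of those pieces in isolation.

## Worked example

Run the end-to-end toy pipeline (12 phantom subjects, ~720 patches, all
eleven stages, ≈2.5 min on one CPU):

```python
from ctsma.pipeline import RunConfig, run_pipeline
run_pipeline(RunConfig(out_dir="runs/demo", seed=1, scale="toy"))
```

or equivalently `ctsma run --config run.yaml`. The run directory then holds
`report.json` (this is the output of seed 1):

```json
{
  "tre_coarse_mm": 1.72,
  "tre_refined_mm": 0.2617,
  "icc": {"bvtv": 0.9118, "tbth_mm": -0.1581,
          "tbsp_mm": 0.8289, "tbn_per_mm": 0.589},
  "icc_overall": 0.5429,
  "classification": {"precision": 1.0, "recall": 1.0, "f1": 1.0, "auc": 1.0},
  "score": {"mae": 0.6564, "r2": 0.8295}
}
```

Reading it: the global rigid fit leaves a mean landmark error of 1.72 mm
across the misaligned cohort, and the bone-wise refinement brings it to
0.26 mm — about a quarter of a CT voxel. The CT student then agrees with
the phantom's exact morphometry at ICC 0.91 for BV/TV on held-out patients;
Tb.Th is essentially unrecoverable from 1-mm CT when the cohort's
trabecular scale varies per subject (see `docs/methods.md`), which is the
point of the MR-guided design. At the patient level the transformer
aggregate separates diseased from normal phantoms perfectly (AUC 1.0 on
the small held-out set of 4) and predicts the continuous severity score
with R² 0.83.

Other entry points: `ctsma phantom`, `ctsma morpho`, `ctsma register`,
`ctsma tre`, `ctsma synth-train/apply`, `ctsma predict`, `ctsma evaluate`.

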