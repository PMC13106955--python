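# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and what the test suite does and does not establish.

## Phantoms: what is emulated

The generator's job is to reproduce the *statistical structure* of a paired
MR/CT knee study, not knee anatomy. A phantom is a thresholded Gaussian
random field: white noise smoothed at a correlation length
`structure_scale` (default 0.35 mm) and binarized, per bone compartment, at
the quantile that delivers the requested bone volume fraction. This yields
interconnected plate/rod-like structures with continuously controllable
BV/TV; thickness and separation co-vary with BV/TV and with the correlation
length, as they do in trabecular bone. Two axis-separated compartments
("femur"/"tibia") with a 5 mm joint gap make articulation unambiguous and
bone masks trivial; landmarks sit at margin-inset compartment box corners so
moderate rigid motions keep them inside the field of view, and their
transformed coordinates are exact, so registration error is measurable
against closed-form ground truth.

The MR-like presentation is the binary microstructure lightly smoothed plus
Gaussian noise (bone bright, voxels 0.234 × 0.234 × 1.5 mm — a 6.4×
anisotropy, handled everywhere in physical units). The CT-like presentation
applies, in order: Gaussian blur of physical width `psf_sigma` (0.8 mm),
resampling to 0.977 × 0.977 × 1.0 mm, a monotone affine intensity remap,
and Gaussian noise (sd 0.05). These defaults were chosen to reproduce the
clinical regime in which trabeculae (50–200 µm in vivo) are far below CT
resolution: with gentler degradation a CT-only regressor recovers the
parameters almost as well as the MR teacher and the cross-modal design has
nothing to contribute.

Cohorts draw a per-subject, per-bone BV/TV target from one of three class
distributions (defaults 0.35 / 0.28 / 0.21, sd 0.01 — bone loss increasing
with grade), an optional per-subject trabecular scale from
`structure_scale_range` (default 0.25–0.45 mm), per-bone rigid
misalignments (≤5°, ≤2.5 mm by default), and a continuous severity score
that is linear in the true regional BV/TV plus noise (sd 0.3). All
randomness flows from one seed through named `SeedSequence` spawns, so any
sub-artifact regenerates bitwise.

What the phantom deliberately does **not** model: knee-shaped geometry,
cartilage, MR physics (no steady-state signal equation), cortical bone,
scanner-specific CT noise texture, and metal/beam-hardening artifacts. A
green suite therefore says the *algorithms* are correct and the *orderings*
(refinement beats global registration, distillation beats no distillation,
transformer beats token-mean) hold under controlled conditions — not that
clinical effect sizes transfer.

## Morphometry

Tb.Th follows the maximal-inscribed-sphere definition: thickness at a voxel
is the diameter of the largest sphere containing it that fits in the
structure; Tb.Sp is the same functional on the marrow phase; Tb.N uses the
plate-model closure BV/TV / Tb.Th, which is deterministic, orientation-free
and internally consistent with the other two. The distance transform runs
in physical millimetres directly on the anisotropic grid (no resampling).
Sphere covering is an exact descending-radius paint (numba-compiled); an
integer `refine` factor subdivides voxels so sphere centres can fall
between voxel centres — at `refine=2` slab phantoms of both parities and
the single-voxel case are recovered exactly, and the suite holds random
patches to a brute-force enumeration oracle within half a voxel diagonal.
Outside a patch each phase is treated as terminated by the other, which
biases thickness low at borders; accuracy tests use interior evaluation.
Patch-level ground truth in the pipeline is computed at native resolution
(`refine=1`) for throughput; the estimator is identical, only sub-voxel
sphere-centre placement is sacrificed, and it is applied consistently to
training and evaluation targets.

MR binarization for operational (non-phantom) inputs uses a per-patch Otsu
threshold with a fixed-threshold override; on phantoms the generator's true
binary is used so regression error is not confounded with binarization
error.

## Registration

The similarity is joint-histogram mutual information in nats (32 bins).
Optimization is delegated to SimpleITK's multi-resolution framework
(Mattes MI, regular-step gradient descent on the 6-parameter rigid group,
shrink factors 2/1, scales from physical shift), single-threaded for
bitwise reproducibility. Regular-step descent is sensitive to its initial
step on small fields of view, so each fit multi-starts over step sizes
(1.0, 0.5) and keeps the candidate with the highest achieved
joint-histogram MI — the objective itself arbitrates. Rotation centre is
the volume's physical centre and is stored in the transform; transforms
serialize to JSON as Euler angles (R = Rz·Ry·Rx), translation, and centre.
Resampling fills out-of-bounds voxels with the moving image's minimum
(air-like), configurable.

Bone-wise refinement estimates one rigid transform per bone on the
mask-restricted metric and composites resampled volumes by mask, zero
outside. On phantoms, cross-modal masked MI shows a genuine ~1° optimum
bias while landmark TRE stays well below one CT voxel; accuracy claims are
therefore stated in TRE, the clinically reported quantity.

## Synthesis (SPSNet)

Two slice-stack generators (2.5D: k=3 adjacent slices in, centre slice out;
small residual encoder–decoders with sigmoid output on per-volume min-max
normalized intensities) and two strided patch discriminators. Losses: the
two-term adversarial objectives in BCE form (non-saturating generator
variant — same optimum, standard stabilization), L1 cycle consistency both
directions (the reverse pass replicates the single synthesized slice into a
k-stack), and a mutual-information structure constraint estimated with a
differentiable Parzen soft histogram (Gaussian kernels, 32 bins, bandwidth
= bin width); the hard-histogram estimator remains the evaluation oracle.
Weights λ_cyc = 1.0, λ_MI = 0.5. Paired geometric augmentation (flips,
in-plane rotations, shifts) is applied identically to both modalities.
Training alternates generator and discriminator Adam updates (lr 2e-4 at
full scale per the training recipe; toy presets use 1e-3 so convergence
fits a few hundred steps). The soft MI estimator is smoothing-biased low;
on independent images it agrees with the hard estimator to well under 0.05
nats, on strongly dependent images it underestimates — acceptable because
only its gradient direction is consumed.

## Distillation (teacher → student)

Teacher: 4-stage-equivalent 3D CNN (three stride-2 convolutions, the first
anisotropic to respect the 6.4× voxel anisotropy, global average pool,
linear head) on 48×48×16 MR patches. Student: the same pattern at 12³ CT
scale (stride 1 then 2, 2). Targets are z-scored per parameter on the
training fold (the four parameters span orders of magnitude in their
units) and inverse-transformed at output. Dropout sits before the head;
weight decay 1e-4. Feature distillation matches the two deepest stages:
both maps are adaptively average-pooled to a common 4³ grid and the student
channels are 1×1-projected to the teacher's; projections train with the
student. Defaults w₁ = 1.0, w₂ = 0.5 per level.

Two empirical findings shaped the defaults, established on validation
cohorts separate from the frozen test conditions:

* **Scheduling matters.** With `L_reg^S + L_d` applied jointly for the whole
  run, the distilled student consistently scored 0.01–0.07 ICC *below* the
  matched no-distillation baseline across every regime tried — with exact
  generative labels and an optimizable baseline, late-phase teacher-matching
  only adds gradient conflict. Applying `L_d` during the first half of the
  epochs and finishing purely supervised (stage-wise hint training,
  `kd_warmup_frac = 0.5`) flips the ordering to a mean gain of +0.03–0.05
  and rescues occasional bad initializations.
* **Feature weight.** At w₂ = 0.1 the transfer effect is below seed noise
  at these widths; 0.5 is the default.

A limit worth stating plainly: distillation cannot create information the
CT patch does not carry. When the cohort's trabecular scale varies freely,
Tb.Th is unidentifiable from 1-mm CT (ICC ≈ 0 for every CT model, teacher
guidance included); the distillation experiments therefore pin the scale so
all four parameters remain partially CT-recoverable, and the pipeline's
default heterogeneous cohort honestly reports the near-zero Tb.Th ICC.

Patch pairing samples candidate centres on a regular grid (half a CT-patch
extent) with jitter bounded so every accepted pair respects the pairwise
box-IoU < 0.5 constraint; greedy acceptance enforces it exactly. Truth is
computed on the 48×48×16 MR-resolution binary footprint at each centre;
degenerate patches are rejected.

## Aggregation

Tokens are the 4 predicted parameters (z-scored with training statistics)
concatenated with a fixed sinusoidal embedding of the patch centre: per
axis, min-max normalized to [−1, 1] over the subject's CT bounds and
encoded at 4 octave frequencies (π/2)·2^j as sin/cos pairs — 24 dims, zero
sin / unit cos at the volume centre, injective on sampling grids. The
encoder is two post-norm transformer layers (d = 32, 4 heads, FF 64,
dropout 0.5), mean-pooled; a 3-class softmax head and a linear score head
share the trunk and train jointly with equal weight (CE + MSE on the
z-scored score). No sequence-order term exists, so the aggregate is exactly
permutation invariant. Subregion centres come from a deterministic in-mask
grid partitioner (snapped to nearest in-mask voxel, refined until k unique
centres exist) — a spatially-distributed-subregions stand-in for
superpixel-style parcellation without its dependency. A token-mean MLP
baseline shares the token construction. Binary OA readout is
p(mild) + p(advanced) from the 3-class head.

## Evaluation

ICC is the two-way random-effects, absolute-agreement, single-measures form
ICC(2,1), computed from ANOVA mean squares and cross-checked against an
independent oracle to 1e-9; "overall" is the unweighted mean of the four
per-parameter ICCs. AUC is rank-based with a patient-level nonparametric
bootstrap CI (2,000 resamples); precision/recall/F1 come from scikit-learn
with undefined-class flagging rather than silent zeros. Folds are
stratified at the patient level; every patch of a subject lives in exactly
one fold. The misalignment-perturbation analysis displaces the *truth
sampling* coordinates by a random direction times the offset (0–15 mm) and
re-scores fixed student predictions — the cheap "re-supervision" variant;
ICC decays monotonically and collapses once the offset exceeds the ~12 mm
patch extent.

## Pipeline and reproducibility

Eleven stages (cohort, coarse registration, synthesis, refined
registration, patch pairs, morphometry truth, teacher, student, tokens,
aggregator, evaluation) execute in dependency order; each writes artifacts
(NIfTI volumes, CSV tables, `.npz` checkpoints with JSON sidecars carrying
config and weight hashes) and records SHA-256 hashes in `manifest.json`.
Re-running with `resume` skips hash-matched stages. Scale presets pin all
problem sizes; "toy" (12 subjects, 60 patches each, 150 GAN steps, widths
4–6, ~2.5 min) is what the tests and the acceptance script run, chosen so
every ordering the package claims is measurable while a full run stays
interactive on one CPU. ITK runs single-threaded and all randomness derives
from the run seed, so a fixed configuration reproduces its outputs exactly.
Deployment path: `ct_only_inference` loads the student and aggregator
checkpoints and produces patient-level outputs from a CT volume and mask
with no MR artifact present.

## Known limitations

* Phantom realism bounds every claim; see above.
* The GAN is small and its toy training is short; synthesis quality is
  judged by structural MI and cycle reconstruction, not radiological
  fidelity.
* The distillation gain at toy scale is a few hundredths of ICC —
  measurable and reproducible across seeds, but far smaller than effects
  reported on clinical data, where references themselves are noisy
  MR-derived measurements.
* ICC confidence intervals are not reported per parameter (only the score
  and AUC carry CIs); fold-level dispersion is available through the
  cross-validation utilities instead.
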