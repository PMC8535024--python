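# Methods

## Pipeline

Each lesion is a two-channel 3D patch (T2W-like, ADC-like). Channels are
min-max normalized to [0, 255] *per patch* — the only self-contained
convention when no cohort-level reference window exists — and quantized
into 64 uniform bins on [0, 256) via `level = floor(v·64/256) + 1`. A
constant channel maps to all level 1 (documented degenerate case). The
combination is invariant to affine rescaling of raw intensities, so the
pipeline does not depend on scanner gain or offset.

### Co-occurrence extraction

Counting is *asymmetric*: ordered pairs along +d only, exactly as the
defining sum is written; the conventional symmetric variant (add the
transpose) is one flag away (`symmetric=True`). Displacement distance is
fixed at one voxel; through-plane offsets also use one slice, i.e. voxels
are treated as an isotropic grid (no inter-slice distance correction).
The 13 canonical directions are the d ~ −d equivalence classes of the 26
unit offsets, represented by the offset whose first nonzero component is
+1, in lexicographic order. Matrices are normalized to probabilities by
default: raw counts scale with lesion volume, and letting patch size leak
into the classifier would contradict the texture rationale (patches are
deliberately *not* resized, so lesions of any size produce the same
26×64×64 input). Voxels inside the rectangular crop but outside any
lesion contour are not masked.

### Haralick features

contrast Σ P(x−y)², correlation Σ P(x−μx)(y−μy)/(σxσy), homogeneity
Σ P/(1+(x−y)²), energy Σ P² (the angular second moment; note some
libraries call √ASM "energy"). Correlation of a zero-variance
(point-mass) matrix is defined as 1. Features are computed per direction
— no directional averaging — giving 4 × 13 × 2 = 104 named features.

### Classifiers

* CNN: two 3×3 stride-1 conv layers (26→32→64 channels, padding 1 so the
  spatial arithmetic is a clean 64→32→16), each with batch normalization
  and ReLU, each followed by 2×2 max pooling (pooling type is a
  convention choice; max is standard for texture nets), then
  flatten → FC 256 → FC 2 → softmax. Loss is class-weighted
  cross-entropy with inverse-class-frequency weights computed on the
  training split; optimizer Adam, lr 10⁻⁵, β₁ = 0.9, β₂ = 0.999,
  200 epochs, batch size 10 (a trailing batch of one sample is skipped —
  batch statistics are undefined for it). After every epoch the
  validation AUC is computed in eval mode (frozen batch-norm statistics)
  and the best-AUC checkpoint is kept; with no validation set (or a
  single-class one) the final epoch is kept. Initialization, shuffling
  and checkpointing are driven by one seed, so training is bit
  reproducible. The network runs on a minimal numpy/numba NN core
  (`radtex.nn`): im2col + GEMM convolutions with analytically derived
  backward passes, verified against finite differences and an
  independent tensor-contraction identity in the test suite. Parameter
  count at defaults: 4,221,282.
* Random forest: 50 trees, gini criterion, nodes expanded until leaves
  are pure, bootstrap resampling; scores are mean leaf probabilities.
* PI-RADS rule: predict csPCa iff PI-RADS ≥ 4. It is a single
  operating point; for AUC purposes its binary prediction is treated as
  a two-level score, the only reading under which the rule has an AUC at
  all. This is stated wherever the number is reported.

### Statistics

AUC is the Mann–Whitney statistic (ties count ½). Its 95% CI is a
percentile bootstrap over lesions (default B = 1000; single-class
resamples are redrawn); clustering of lesions within patients is ignored
at this stage, matching the lesion-level unit of analysis. Operating
points maximize the Youden index over observed scores (ties: higher
sensitivity, then lower threshold); thresholds are selected on the full
evaluation set and reused within subgroups, and can instead be supplied
externally (e.g. validation-selected) for honest deployment estimates.
Sensitivity/specificity/PPV/NPV intervals are Wald (z = 1.96), clipped to
[0, 1]. Paired AUCs are compared with the fast DeLong test on midrank
structural components (cross-checked in the tests against R pROC on a
frozen dataset and against a lesion-level bootstrap variance); paired
sensitivities and specificities with McNemar's test — exact binomial when
the discordant count is below 25, chi-square with continuity correction
otherwise; zero discordance gives p = 1. No multiple-testing correction
is applied. Subgroups with one class are reported as not-evaluable rather
than erroring.

A calibration caveat measured by the test suite and the acceptance
script (1000 null replicates of 100 paired lesions): the exact /
continuity-corrected McNemar variant is conservative for discrete data —
its rejection rate at α = 0.05 falls below the nominal level (≈ 0.03–0.04
depending on the run's seed) — while the DeLong test is close to nominal
(≈ 0.04–0.055).

## Phantom generator

Each lesion patch is a Gaussian random field: white noise convolved with
an isotropic Gaussian kernel whose sigma is class dependent
(csPCa-like 0.7 voxels — fine-grained heterogeneity; benign-like 2.5 —
smooth), min-max stretched to [0, 255], plus for csPCa a central
spherical core (radius 0.3 × min dimension) with a 40% intensity drop in
the ADC-like channel, plus additive Gaussian noise (SD 5 intensity
units). Patch shapes are drawn per lesion from 8–24 voxels per axis and
never resized — the classifiers consume fixed-size GLCMs, not images.
Anisotropic voxels are not modeled.

Cohort composition mirrors a prostatectomy cohort: 402 patients by
default with 1–2 lesions each (extra-lesion probability 0.16, giving
≈ 1.16 lesions/patient, ≈ 466 lesions), csPCa prevalence 0.65 (or exact
class counts when specified), zones PZ/TZ/AFS at 0.78/0.21/0.01,
solitary/multifocal at 0.41/0.59, PSA lognormal with median ≈ 8 ng/mL.
Synthetic PI-RADS scores are drawn from a class-conditional table with
P(≥4 | csPCa) = 0.83 and P(≥4 | non-csPCa) = 0.53, so the rule baseline
has realistic sensitivity/specificity. One lesion per patient (first
csPCa, else first) is flagged as the index lesion. Splits are assigned at
the patient level by shuffling and largest-remainder rounding of the
60/10/30 fractions, so no patient straddles splits and counts are within
one patient of nominal.

What the phantoms do *not* emulate: MR physics, diffusion decay,
anatomy, registration error, intra-class texture diversity, or any
correlation structure between texture and the metadata beyond the label.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers a *constructed* texture-heterogeneity
signal; they say nothing about clinical discrimination on real mpMRI.

## Problem sizes and numerical choices

The end-to-end study in the tests and the acceptance script uses 400
synthetic patients (≈ 465 lesions, ≈ 280 training), 200 training epochs
— about 10 minutes on one CPU, dominated by CNN training. Calibration
simulations use 1000 nulls of 100 lesions; bootstrap coverage uses 500
cohorts of 150 lesions with B = 1000. The NN core computes in float32
(loss/softmax in float64); batch-norm epsilon 1e-5, momentum 0.1; Adam
epsilon 1e-8; pooling ties route the gradient to the first matching
window position, deterministically. GLCM bincount accumulation is exact
integer arithmetic.

## Known limitations

* The CNN's FC widths, pooling type, padding, and checkpoint-selection
  metric are conventions chosen here (256, max, 1, validation AUC);
  alternatives are configurable but not swept.
* Bootstrap and DeLong treat lesions as independent; patients
  contributing two lesions mildly violate this.
* The PI-RADS rule's "AUC" is the two-level-score reading; it is not
  comparable to a continuous ROC in any finer sense.
* The phantom task is easy by construction at default contrast; the
  learned models saturate near AUC 1, so relative rankings among the
  learned models on phantoms are not meaningful.
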