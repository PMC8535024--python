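# radtex

Texture-based classification of clinically significant prostate cancer
(csPCa) from paired T2-weighted / ADC lesion patches, built around 3D
gray-level co-occurrence matrices (GLCMs).

## Who this is for

Researchers in prostate mpMRI radiomics who want a self-contained,
reproducible implementation of GLCM-texture lesion classification — the
learned-texture route (a compact CNN reading raw co-occurrence matrices),
the handcrafted route (Haralick features + random forest), and the
radiologist-score baseline (PI-RADS ≥ 4 rule) — together with the paired
statistics needed to compare them. Because clinical cohorts of this kind
are not publicly shareable, the package includes a seeded phantom
generator that emulates a labeled prostatectomy cohort, so the whole
pipeline runs and is testable offline.

## The method

For a lesion patch *f* quantized to *n* = 64 gray levels (values 1..64),
the co-occurrence matrix along displacement *d* = (di, dj, dk) is

```
GLCM_d(x, y) = #{ (i,j,k) : f(i,j,k) = x  and  f(i+di, j+dj, k+dk) = y }
```

The 26 unit-neighbor displacements in {−1,0,1}³ reduce to 13 directions
under d ~ −d. One 64×64 matrix per direction per modality (T2W, ADC)
yields a 26-channel stack, normalized to probabilities. Two classifiers
consume it:

* **GLCM CNN** — conv(26→32, 3×3) + BN + ReLU → pool 2×2 →
  conv(32→64) + BN + ReLU → pool 2×2 → FC 256 → FC 2 → softmax; trained
  with class-weighted cross-entropy, Adam (lr 10⁻⁵, β = (0.9, 0.999)),
  200 epochs, batch size 10, keeping the epoch with the best validation
  AUC. The network is implemented in a minimal numpy NN core
  (`radtex.nn`), no deep-learning framework required.
* **Haralick random forest** — contrast, correlation, homogeneity and
  energy per directional matrix (4 × 13 × 2 = 104 features), fed to a
  50-tree gini forest with pure-leaf expansion and bootstrap sampling.

Evaluation is lesion-level: Mann–Whitney AUC with a 1000-resample
percentile bootstrap CI, Youden-index operating points, Wald CIs for
sensitivity/specificity, paired DeLong tests for AUC differences,
McNemar tests for sensitivity/specificity differences, and subgroup
reports (prostate zone, focality, PI-RADS score, index lesions by PSA
stratum).

## Worked example

```python
from radtex import (PhantomConfig, generate_cohort, split_cohort,
                    GLCMTransformer, HaralickTransformer,
                    GLCMConvNetClassifier, train_rf, predict_rf,
                    pirads_cla, auc)
import numpy as np

patches, records = generate_cohort(PhantomConfig(n_patients=60, seed=1))
records = split_cohort(records, seed=1)

stacks = GLCMTransformer().fit(patches).transform_stacks(patches)
X = np.stack([s.matrices for s in stacks]).astype("float32")
features = HaralickTransformer().fit(stacks).transform(stacks)

y = records["label"].to_numpy()
tr = (records["split"] == "train").to_numpy()
va = (records["split"] == "validation").to_numpy()
te = (records["split"] == "test").to_numpy()

cnn = GLCMConvNetClassifier(epochs=20, random_state=0).fit(X[tr], y[tr], X[va], y[va])
forest = train_rf(features[tr], y[tr])

print("CNN test AUC:   ", round(auc(cnn.predict_proba(X[te])[:, 1], y[te]), 3))
print("RF test AUC:    ", round(auc(predict_rf(forest, features[te]), y[te]), 3))
print("PI-RADS rule AUC:", round(auc(pirads_cla(records[te]).astype(float), y[te]), 3))
```

Output (fixed seeds):

```
CNN test AUC:    1.0
RF test AUC:     1.0
PI-RADS rule AUC: 0.773
```

The two texture classifiers separate the heterogeneous (csPCa-like) from
the smooth (benign-like) phantoms perfectly at this easy default
contrast, while the rule baseline only tracks the noisy synthetic
PI-RADS metadata (on this small 19-lesion test split its AUC is itself
noisy; at full cohort size it settles near 0.6–0.65).

There is also a CLI covering each stage
(`radtex generate | extract | features | train-cnn | train-rf | evaluate |
compare | run-all`); `radtex run-all --config cfg.yaml --out results/`
runs everything deterministically from one YAML file.

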