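# burntex

Texture-based classification of burn severity from B-mode-style greyscale
images.

Thermal damage changes how soft tissue scatters ultrasound: vapour-filled
pores and degraded microstructure show up in B-mode images as low-intensity
speckle regions that grow in number and size with burn severity, appearing
progressively along the imaging depth.  `burntex` quantifies that texture
change and classifies it.  It is aimed at researchers working on quantitative
ultrasound tissue characterization who need a reproducible, leakage-free
reference pipeline — and, because clinical and *ex vivo* burn imaging
datasets are rarely shareable, it ships a synthetic speckle-phantom generator
so every stage can be exercised and tested without access to real data.

## Method

1. **GLCM texture features.** Each image `I(m, n)` with `L` grey levels is
   reduced to a grey-level co-occurrence matrix
   `χ_{k,l}(i, j) = #{(m, n) : I(m, n) = i, I(m+k, n+l) = j}` for a pixel
   offset `(k, l)` (default `(0, 1)`, horizontally adjacent pixels).  The
   normalized matrix `p(i, j) = χ(i, j) / Σχ` is summarized by 19 second-order
   (Haralick-family) statistics — contrast `Σ(i−j)²p`, correlation,
   homogeneity `Σp/(1+(i−j)²)`, energy, entropy, sum/difference statistics,
   the information measures of correlation, and so on (see
   `docs/methods.md` for the full catalog).
2. **Feature selection.** Sequential backward selection discards the least
   discriminatory feature per stage, scored by the mean leave-one-out
   cross-validated (LOOCV) accuracy of the six pairwise classifiers, and
   stops when any further removal would increase the classification error.
3. **Classification.** Pairs of burn groups are separated by a soft-margin
   RBF-kernel SVM (+1 = null-hypothesis group; the signed decision value is
   the classification score).  All groups at once are classified by kernel
   Fisher discriminant analysis (KFDA): the Fisher criterion solved in the
   RBF feature space yields up to `C−1` discriminant scores, and a sample is
   assigned to the nearest class centroid in score space.
4. **Assessment.** LOOCV with per-fold min–max renormalization (the held-out
   sample never influences its own scaling), aggregated confusion matrices
   with accuracy / sensitivity / specificity, repeated stratified 90/10
   Monte-Carlo splits, and the diagnostic-test minimum-sample-size formula
   `n = max(z² sₙ(1−sₙ)/(d²P), z² s_p(1−s_p)/(d²(1−P)))`.

## Worked example

Generate the default four-class phantom dataset (30 images per class,
severities 0, ⅓, ⅔, 1), extract the 19 texture features, and assess the
classifiers:

```python
from burntex import (generate_dataset, extract_feature_matrix, loocv_binary,
                     loocv_multiclass, monte_carlo_eval, all_class_pairs,
                     SampleSizeSpec, min_sample_size)

manifest, images = generate_dataset(n_per_class=30, seed=0)
features = extract_feature_matrix(
    [images[k] for k, _ in manifest.entries],
    [label for _, label in manifest.entries],
)
for a, b in all_class_pairs(features.labels):
    cm, measures, _ = loocv_binary(features.restrict_labels((a, b)), positive_label=b)
    print(f"{a} vs {b}: accuracy {measures.accuracy:.2f} "
          f"sensitivity {measures.sensitivity:.2f} specificity {measures.specificity:.2f}")
cm, per_class, overall = loocv_multiclass(features)
print(f"multiclass LOOCV overall accuracy: {overall:.3f}")
mc_mean, _ = monte_carlo_eval(features, train_fraction=0.9, repetitions=100, seed=0)
print(f"Monte Carlo mean accuracy (100 x 90/10): {mc_mean:.3f}")
spec = SampleSizeSpec(sensitivity=0.95, specificity=0.95, prevalence=0.4, margin=0.1, z=1.96)
print(f"minimum sample size: {min_sample_size(spec)}")
```

prints

```
severity_0.00 vs severity_0.33: accuracy 1.00 sensitivity 1.00 specificity 1.00
severity_0.00 vs severity_0.67: accuracy 1.00 sensitivity 1.00 specificity 1.00
severity_0.00 vs severity_1.00: accuracy 1.00 sensitivity 1.00 specificity 1.00
severity_0.33 vs severity_0.67: accuracy 0.97 sensitivity 0.97 specificity 0.97
severity_0.33 vs severity_1.00: accuracy 1.00 sensitivity 1.00 specificity 1.00
severity_0.67 vs severity_1.00: accuracy 0.98 sensitivity 1.00 specificity 0.97
multiclass LOOCV overall accuracy: 0.992
Monte Carlo mean accuracy (100 x 90/10): 0.991
minimum sample size: 46
```

Adjacent severity grades are the hard comparisons (a few misclassified
samples each); well-separated grades classify perfectly, and the Monte-Carlo
estimate agrees with LOOCV to a tenth of a point.  The sample-size line says
46 samples suffice to establish 95% sensitivity and specificity to within a
±0.1 margin at 40% prevalence and 95% confidence — which the default 60
samples per pair satisfy.

The same workflow is available from the shell:

```sh
burntex simulate --classes 4 --n 30 --out data/ --seed 7
burntex extract --manifest data/manifest.csv --out features.csv
burntex select --features features.csv --out trace.json
burntex pairwise --features features.csv --pos severity_1.00 --neg severity_0.67 --report report.json
burntex multiclass --features features.csv --report multiclass.json
burntex montecarlo --features features.csv --reps 100 --seed 17
burntex samplesize --sn 0.95 --sp 0.95 --d 0.1 -p 0.4
burntex run --manifest data/manifest.csv --mode pairwise --out results/
```

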