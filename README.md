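# restcombine

Binary classification from resting-state fMRI rarely hinges on a single
derived measure: amplitude maps, local synchrony, homotopic coupling and
connectivity matrices each carry partly complementary group information.
`restcombine` implements three fusion strategies for combining many
resting-state feature types around an RBF-kernel support vector machine,
together with the feature extractors, nested cross-validated feature
selection, and significance machinery needed to evaluate them end to end.
It is aimed at researchers who want a transparent, leakage-free reference
implementation of multi-feature rs-fMRI classification that can be
exercised entirely on synthetic data.

## What it computes

**Eleven feature types** per subject, reduced to ROI features over an
integer atlas volume:

* local measures — ALFF (mean FFT amplitude over 0.01–0.1 Hz, normalised to
  brain mean 1), ReHo (Kendall's W over a voxel and its 26 neighbours),
  VMHC (Fisher-z correlation with the mirror-symmetric counterpart), FCS
  (mean Fisher-z correlation with all other gray-matter voxels);
* network measures — five seed-network maps (Fisher-z correlation against a
  pooled bilateral seed reference: DMN, ECN, SN, LN, StrN analogues), ROI-pair
  temporal correlation `z(r_ij)` (lower triangle), and pairwise Granger
  causality F-statistics (bivariate VAR, order by AIC, all ordered pairs).

**Selection**: features ranked by absolute pooled two-sample t-score; the
kept percentage (1–50%), SVM trade-off `C ∈ {2^-4..2^6}` and RBF width
`γ ∈ {2^-10..2^3}` are chosen jointly by stratified inner 10-fold CV, with
ranking and standardisation recomputed inside every inner fold. The inner
accuracy `Acc_m` of each feature type m is recorded.

**Three fusion frameworks**, evaluated by balanced outer 10-fold CV:

1. *feature combination* — selected features concatenated into one vector,
   single RBF-SVM;
2. *kernel combination* — per-type RBF Gram matrices mixed as
   `K = Σ_m β_m K^(m)`;
3. *classifier combination* — per-type SVMs fused by weighted voting,
   `ŷ = sign(Σ_m β_m f_m(x))`;

with the accuracy-derived weights

```
β_m = (Acc_m − 0.5) / Σ_{i: Acc_i > 0.5} (Acc_i − 0.5)   if Acc_m > 0.5,
β_m = 0                                                   otherwise,
```

so sub-chance feature types are excluded and `Σ β_m = 1`.

**Evaluation**: sensitivity, specificity, accuracy, precision and F score
from pooled outer confusion counts, and a 1,000-repeat permutation
empirical null that thresholds per-feature selection counts across folds
and frameworks at P < 0.05.

A synthetic cohort generator produces balanced two-group voxel-level
cohorts (band-limited ROI latents, motion traces, WM/CSF nuisance
ensembles) with controllable group effects targeting any feature type, so
the entire pipeline is testable without any scan data.

## Worked example

```python
import restcombine as rc

spec = rc.CohortSpec(
    n_per_group=20, grid_shape=(8, 8, 8), n_rois=8, n_timepoints=120,
    effects=(rc.EffectSpec("TC", (1, 2), 0.8),
             rc.EffectSpec("ALFF", 3, 1.5)),
    seed=7)
seed_map = rc.default_seed_map(8)
feature_sets = [
    rc.extract_features(rc.preprocess_subject(s),
                        feature_types=("ALFF", "TC"), seed_map=seed_map)
    for s in rc.generate_cohort(spec)
]
grids = rc.SelectionGrids(percents=(10, 30, 50), c_grid=(0.25, 1.0, 4.0),
                          gamma_grid=(2**-4, 2**-2, 1.0), inner_k=5)
results = rc.run_experiment(
    feature_sets, frameworks=("feature", "kernel", "classifier"),
    grids=grids, outer_k=10, seed=7)
for tag, res in results.items():
    m = res.metrics
    print(f"{tag:12s} acc={m.accuracy:.3f} sens={m.sensitivity:.3f} "
          f"spec={m.specificity:.3f}")
```

prints

```
feature      acc=0.900 sens=0.950 spec=0.850
kernel       acc=1.000 sens=1.000 spec=1.000
classifier   acc=0.975 sens=0.950 spec=1.000
```

Both planted effects are deliberately strong (the amplitude effect scales
the target ROI's signal ×2.5; the coupling effect adds ≈0.4 correlation to
one ROI pair), so on this 40-subject cohort every fusion framework
separates the groups nearly perfectly; with `effects=()` the same pipeline
hovers around 50% accuracy, as it must under the null.

The same pipeline is available from the shell:

```
restcombine simulate --out cohort/ --seed 7 --effect TC:1,2:0.8
restcombine extract  --cohort cohort/cohort.json --out feats/ --types ALFF,TC
restcombine classify --features feats/features.json --framework kernel \
                     --out results/kernel.json --seed 7
restcombine report   --results results/kernel.json
```

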