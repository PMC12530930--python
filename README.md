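# soilprint

UPLC-PDA fingerprint profiling of soil nonvolatile metabolites, built as a
reusable Python library around the workflow used to trace the geographic
origin of tobacco-planting soils in Guizhou: three origin classes — the
honey-sweet regions MT I and MT II and the fresh-sweet region QT, six
soils each — profiled at 230 nm over a 17-minute gradient, with the
analyte peaks concentrated in the 4–12 min window.

The package is for analysts who want to run or study this kind of
fingerprint workflow end to end without access to raw instrument data: a
synthetic-cohort generator plants known regional structure (30 common
metabolite peaks, 17 of them with region-specific abundance shifts,
retention-time drift and jitter, baseline and detector noise calibrated
to realistic replicate precision), and every downstream stage is a tested
library function.

## The methods at its core

* **Fingerprint construction** — baseline correction (asymmetric least
  squares), peak detection and valley-to-valley trapezoid integration,
  multipoint (piecewise-linear) retention-time correction on anchor
  peaks, cross-sample peak matching, and extraction of the *common
  peaks* present in every sample.
* **Similarity index** — each sample's common-peak area vector is scored
  against the *average fusion vector* reference fingerprint
  (the per-peak mean), by Pearson correlation (default) or cosine.
* **Chemometrics** — PCA; PLS-DA by NIPALS against a centred one-hot
  class indicator with R²Y and venetian-blind cross-validated
  Q² = 1 − PRESS/SS; a label-permutation test (200 iterations) with
  R²/Q² regression intercepts; VIP scores
  VIP_j = √( p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a ); characteristic
  peaks selected by VIP > 1.0 ∧ ANOVA p < 0.05.
* **Origin tracing** — Fisher linear classification functions
  Y_k(x) = b_k·x + c_k with b_k = S⁻¹μ_k and
  c_k = −½ μ_kᵀS⁻¹μ_k + ln π_k (pooled within-class covariance S,
  shrinkage-regularized), leave-one-out cross-validation, hierarchical
  clustering (Euclidean, Ward) and external-sample validation.
* **Soil statistics** — one-way ANOVA (from raw data or printed
  mean ± SD summaries), Duncan's multiple range test with letter
  displays, and marker-vs-physicochemical Pearson correlation tables.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from soilprint.pipeline import RunConfig, build_fingerprint, process_chromatograms
from soilprint.chemometrics import fit_plsda
from soilprint.simulate import simulate_cohort

config = RunConfig(seed=42)
chroms, truth = simulate_cohort(config.simulation)
tables = process_chromatograms(chroms, config)
aligned, matrix, reference, similarity = build_fingerprint(tables, config)
print(len(matrix.peak_ids))                         # 30
print(round(similarity["pearson"].min(), 3),
      round(similarity["pearson"].max(), 3))        # 0.824 0.946
model = fit_plsda(matrix.areas.to_numpy(), matrix.labels())
print(round(model.r2y, 3), round(model.q2, 3))      # 0.977 0.936
```

All 30 planted peaks are recovered as common peaks; the similarity
indices (0.824–0.946 here) say every soil shares the cohort's chemical
composition while differing in content distribution; R²Y ≈ 0.98 and
Q² ≈ 0.94 mean the two-component PLS-DA fits and predicts the region
labels far above the Q² > 0.5 gate.

The `examples/` directory walks through each capability — cohort
simulation, fingerprint + similarity, marker selection with permutation
validation, Fisher-function origin tracing with external samples, and
soil ANOVA/Duncan/correlation — each printing its numbers with a note on
what they mean. A thin CLI mirrors the pipeline
(`soilprint run-all --seed 42 --outdir out/`).

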