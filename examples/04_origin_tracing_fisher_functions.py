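"""Trace geographic origin with Fisher linear classification functions.

Fits one linear score function per region on the characteristic-peak
areas, prints them in the conventional Y1/Y2/Y3 layout, cross-validates
by leave-one-out, clusters the cohort hierarchically, and classifies
four held-out external soils.
"""

import warnings

import numpy as np

from soilprint.classification import (
    ConfusionMatrix,
    accuracy,
    adjusted_rand_index,
    classify,
    cross_validate,
    fit_lda,
    hca,
)
from soilprint.chemometrics import (
    fit_plsda, peak_anova_pvalues, select_markers, vip_scores,
)
from soilprint.pipeline import (
    RunConfig,
    build_fingerprint,
    extract_feature_vector,
    process_chromatograms,
    render_discriminant_functions,
)
from soilprint.fingerprint import alignment_maps, correct_retention, select_anchors
from soilprint.simulate import simulate_cohort, simulate_external_samples

warnings.simplefilter("ignore")

config = RunConfig(seed=42)
chromatograms, _ = simulate_cohort(config.simulation)
tables = process_chromatograms(chromatograms, config)
_, matrix, reference, _ = build_fingerprint(tables, config)

model_pls = fit_plsda(matrix.areas.to_numpy(), matrix.labels())
markers = select_markers(matrix.peak_ids, vip_scores(model_pls),
                         peak_anova_pvalues(matrix)).selected_ids

X = matrix.areas[markers].to_numpy()
labels = matrix.labels()
lda = fit_lda(X, labels, feature_ids=markers)
print("fitted classification functions (one per region):")
print(render_discriminant_functions(lda))

yhat, _ = classify(lda, X)
cm = ConfusionMatrix.from_predictions(labels, yhat, lda.classes, "training")
print(f"\ntraining accuracy: {accuracy(cm):.1f}% "
      f"(diagonal {np.diag(cm.counts).tolist()})")
cv = cross_validate(X, labels)
print(f"leave-one-out accuracy: {accuracy(cv):.1f}%")

tree = hca(X, k=3, sample_ids=matrix.sample_ids)
print(f"HCA (ward/euclidean) at k=3: adjusted Rand index vs regions = "
      f"{adjusted_rand_index(tree.assignments, labels):.2f}")

ext_chroms, _ = simulate_external_samples(config.simulation)
ext_tables = process_chromatograms(ext_chroms, config)
anchors = select_anchors(tables, k=config.n_anchors)
idx = [matrix.peak_ids.index(m) for m in markers]
print("\nexternal validation:")
for t in ext_tables:
    amap = alignment_maps([t], anchors,
                          registration_rts=tables[0].apex_rts)[t.sample_id]
    vec = extract_feature_vector(correct_retention(t, amap),
                                 matrix.consensus_rts, config.match_tol_min,
                                 fallback=reference.mean_areas)
    pred, _ = classify(lda, vec[idx])
    flag = "ok" if pred == t.group else "MISS"
    print(f"  {t.sample_id}: true {t.group:6s} -> predicted {pred:6s} [{flag}]")
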