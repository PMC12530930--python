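# Methods

This note documents the models, algorithms and numerical choices behind
`soilprint`, in the order data flows through the pipeline.

## Synthetic cohorts

The generator emulates a three-region soil study: UPLC-PDA traces at
230 nm, 17 min long, sampled at 5 points/s (≥ 10 points across the
narrowest peak), with 30 analyte peaks confined to the 4–12 min window.
Groups are MT I, MT II and QT with six samples each.

**Peak positions.** Metabolite retention times occupy an inner margin of
the window (0.25 min from the lower edge, 0.35 min from the upper) so
that drifted apexes stay inside the half-open integration window. Gaps
between neighbours are a guaranteed 0.22 min minimum plus exponentially
distributed slack. Two reasons: real gradient separations show irregular
spacing, and an evenly spaced grid is information-free for drift
registration — a whole-axis shift by one peak would look self-consistent.

**Peak shape.** Exponentially modified Gaussian with σ = 0.03 min and
τ = σ/2 (realistic tailing), via `scipy.stats.exponnorm`; a pure Gaussian
is selectable. Kernels are evaluated on a ±(8σ + 12τ) window, keeping
each noise-free kernel's trapezoid integral within 0.5% of its nominal
area.

**Abundances.** Base areas are log-uniform on 5–80 mAU·min (right-skewed,
strictly positive). Per sample, log2 areas receive N(0, 0.28) biological
variation plus the group's marker fold change, and all areas share a
per-injection scale factor exp(N(0, 0.009)) — the dominant term in
replicate area RSDs, standing in for injection-volume variability.
Detector noise is i.i.d. N(0, 0.5 mAU); the baseline is a slow
polynomial (2.0 + 0.3t − 0.015t², mAU).

**Markers.** Seventeen of the 30 metabolites (peaks 3, 4, 6, 9, 10, 13,
14, 16, 18, 19, 21, 22, 23, 25, 28, 29, 30) carry region-specific log2
offsets of 0.25–1.2. The sign pattern follows the study system's
qualitative ordering (most markers higher in the honey-sweet soils,
peaks 3 and 9 higher in the fresh-sweet soils, the MT I/MT II contrast
alternating by peak); the magnitudes are free parameters calibrated
once, jointly with the abundance spread and biological SD, so that
cohort similarity indices span the 0.80–0.96 band reported for regional
soil fingerprints while markers remain clearly separable (Q² ≳ 0.85,
15–17/17 recovered).

**Retention-time errors.** Each sample draws an affine drift (offset
SD 0.05 min, slope SD 0.005) plus per-peak jitter N(0, 0.015 min)
truncated at ±2 SD — instrument RT wander is bounded, and an untruncated
tail occasionally fused neighbouring peaks the emulated separation
resolves. The affine-plus-jitter model deliberately requires multipoint
(piecewise) correction rather than a single shift.

**QC replicates** share one fixed peak profile (no biological term) and
differ only in jitter, injection scale and noise. With the defaults,
five-replicate area RSDs are typically 1–2% per peak (worst observed
2.1% over 40 seeds) and RT RSDs below 0.7%, comfortably inside the
< 2.75% / < 2.14% repeatability envelope the emulated instrument
reports.

**Soil tables** draw each of the eight standard variables (TN, TP, TK,
AHN, AP, AK, OM, pH) independently from the per-region normal summaries
in `soilprint.reference_data`; pH is truncated to [3, 10] by rejection.

All randomness flows through `numpy.random.SeedSequence` with fixed
spawn keys, so identical configurations are bit-identical, and the
pipeline fans a single global seed out per stage so disabling one stage
never perturbs another.

What the generator does **not** emulate: co-eluting peaks requiring
deconvolution, wavelength dimension (single-channel only), gradient
program artefacts, missing or extra peaks between samples, heavy-tailed
noise, or between-day effects. Passing tests therefore demonstrate the
pipeline's correctness and its behaviour under realistic *well-behaved*
data, not robustness to pathological chromatography.

## Processing

Baseline: asymmetric least squares (Whittaker smoother with asymmetry
p = 0.001, penalty λ = 1e9, 10 reweighting iterations) solved with a
pentadiagonal banded solver. The stiff penalty (bend scale ≈ 0.6 min)
follows the run-scale baseline but cannot dip between closely spaced
peaks, where a softer fit would ride up variably and corrupt replicate
precision; the cost is a small tracking offset (≈ 0.1 mAU on the default
baseline, well below detector noise). A rolling-minimum baseline is
available as an alternative.

Detection: maxima on a Savitzky–Golay smoothed copy (width 7, order 2,
detection only) with height ≥ SNR·noise, noise estimated as
1.4826·MAD(Δy)/√2 — robust to the sparse peaks. Integration bounds walk
from the apex to the flanking valley, tracking the running minimum and
stopping at the first rise exceeding half the noise SD (or a 0.3-min
cap); equal-valued valleys resolve to the one nearer the apex. Areas are
valley-to-valley trapezoids on the *unsmoothed* corrected trace. A
drop-line chord subtraction was evaluated and rejected: it cancels
smooth baseline residuals but skims real mass whenever a bound is a true
overlap valley. The integration window is half-open, [lo, hi): an apex
exactly at the upper edge is excluded.

Precision reports compute RSD% = 100·SD/mean of apex RT and area per
peak over replicate injections, for peaks matched (via the fingerprint
matcher) in every replicate; unmatched peaks are dropped with a warning.

## Alignment and the fingerprint

Drift registration is the step that breaks first on realistic data:
with drift approaching half the peak spacing, nearest-peak matching
mis-registers entire samples by one peak. Each sample is therefore
registered against a dense reference peak list (the first sample's
apexes) by scanning candidate offsets over ±0.3 min and minimizing the
capped (0.08 min) mean nearest-distance — the irregular peak spacing
makes the true register the unique minimum — followed by two rounds of
least-squares affine (offset + slope) refinement on the matched pairs.

Anchors are k = 5 peaks present in every sample (within half the coarse
tolerance after registration), spread evenly over the RT range,
preferring taller (median height) candidates. Each sample's
piecewise-linear warp maps its observed anchor RTs onto the anchor
consensus; outside the anchor span the terminal segment's slope
continues (no discontinuities). Warping changes retention coordinates
only, never areas or heights.

Matching clusters all warped apexes in (RT, sample id) order: a new
cluster opens when the gap to the running cluster's consensus (mean)
exceeds the tolerance (default 0.10 min — several times the residual
jitter, well under the minimum peak spacing); within a cluster a sample
keeps its nearest peak and the loser seeds a new cluster. The sort key
makes results independent of sample order. Common peaks are clusters at
presence ≥ 1.0 (all samples) by default, re-indexed P1..Pm by consensus
RT.

The reference fingerprint is the arithmetic column mean (the average
fusion vector); similarity is Pearson correlation by default — the
similarity index tradition speaks of a "related coefficient" — with
cosine reported alongside, and an optional total-area normalization flag
(off by default: only retention times are normalized in the emulated
workflow, not areas).

## Chemometrics

PCA operates on the autoscaled (unit-variance) matrix via SVD; explained
percentages are squared singular values over their total. Autoscaling is
also the PLS-DA default, matching common chemometrics practice for peak
tables whose areas span an order of magnitude; center-only is available.

PLS-DA is classic NIPALS PLS2 against the centred one-hot class
indicator (convergence 1e-10, ≤ 500 iterations per component,
deflation of X and Y, sign convention: first non-negligible weight
element positive). The default component count is min(2, classes − 1);
`choose_components` implements the first-local-maximum-of-Q² rule for
users who want it data-driven. Q² uses venetian-blind folds (sample
index mod 7), refitting scaling and model per fold and pooling PRESS
over folds against the total centred Y sum of squares. Requesting more
components than the rank bound truncates with a warning; a fold whose
training set drops to a single-member class warns.

VIP follows the standard per-component explained-Y weighting; ΣVIP² = p
holds to machine precision and is asserted in tests. The permutation
test permutes labels uniformly (a permutation identical to the original
is a valid draw), refits with the same component count, records the
Pearson correlation between permuted and original centred indicator
matrices, and reports the intercepts of least-squares lines of R²Y and
Q² against that correlation, with the original model entering at
correlation 1.

Characteristic peaks require **strictly** VIP > 1.0 and one-way ANOVA
p < 0.05 across groups, the ANOVA computed on log2 areas by default
(areas are log-normal by construction).

## Classification

Fisher linear classification functions: b_k = S⁻¹μ_k,
c_k = −½μ_kᵀS⁻¹μ_k + ln π_k with equal priors by default. With 17
features and only 15 pooled within-class degrees of freedom the pooled
covariance is singular, so shrinkage S + λ·tr(S)/p·I with λ = 0.01 is
the default; a pseudo-inverse and an unregularized mode (which raises a
named error when S is ill-conditioned) are selectable. Ties in the
argmax break to the earlier class with a warning. Cross-validation
defaults to leave-one-out; an interleaved k-fold is available.
Functions render in the conventional printed layout
(`Y1=43.811X3−…−88.429`) and parse back to 3 decimals.

Hierarchical clustering uses `scipy.cluster.hierarchy` (Euclidean
distance; Ward linkage by default, consistent with compact regional
clusters; average/complete selectable) on autoscaled features, cut by
`fcluster` at the requested k; tests verify the merge heights against a
brute-force Lance–Williams agglomeration.

A caveat worth stating: leave-one-out on balanced classes is slightly
pessimistic under the null (excluding the held-out sample weakens its
own class mean), so chance-level LOO accuracy sits a little below 1/k.

## Soil statistics

`anova_from_summary` reconstructs SSB/SSW from printed (mean, SD, n)
triplets and is algebraically identical to the raw-data path, which lets
published region summaries be tested directly — e.g. the pH summaries
give F = 9.39, p = 0.0023 (all three regions distinct) while total
phosphorus gives p = 0.26 (no separation), matching their published
letter patterns. Degenerate inputs: SSW = 0 with SSB > 0 yields F = ∞,
p = 0; SSW = SSB = 0 raises a named error.

Duncan's multiple range test computes least significant ranges from
studentized-range quantiles at the protection level
α_p = 1 − (1 − α)^(p−1) (validated against published table values at
df = 15), uses the harmonic mean of group sizes when unbalanced
(Kramer adjustment), and assigns letters by marking maximal
non-significant ranked windows — windows inside a wider non-significant
window inherit non-significance, per Duncan's protection rule.

Marker-vs-soil correlations are Pearson r with two-sided t-based
p-values on log2 areas by default; constant columns yield flagged NaN
cells rather than errors.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the
study's own scale (18 samples × 5101 points, 30 peaks): one cohort
analysis takes about a second, so the stochastic suites use 20-seed
panels for recovery checks, 40 seeds for QC-precision characterization
during development, 2000 replicates for ANOVA type-I calibration and
200 permutations for the permutation test — comfortably small for a
laptop while large enough for the stated statistical bands.

## Known limitations

Overlapping peaks are integrated valley-to-valley, splitting shared mass
at the valley rather than deconvolving; the similarity index inherits
Pearson correlation's sensitivity to the few largest peaks; the
permutation-line intercepts depend on the permutation-correlation
design (SIMCA's exact construction is unpublished, so values are
comparable qualitatively, not numerically); and the published
discriminant-function coefficients cannot be re-derived because the
underlying peak areas are unpublished — the package evaluates and
renders them but fits its own functions on synthetic cohorts.
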