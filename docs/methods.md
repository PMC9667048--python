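# Methods

`petdx` implements an automated differential-diagnosis pipeline for the four
diagnostic groups AD (Alzheimer's dementia), DLB (dementia with Lewy
bodies), FTD (frontotemporal dementia) and NC (normal controls), operating
on FDG-PET-like 3-D uptake volumes. This note documents the models, the
parameters that matter, the synthetic data the pipeline is validated on,
and the numerical choices that pin down bit-reproducibility.

## Preprocessing

Every scan is restricted to a binary brain mask, smoothed with an isotropic
3-D Gaussian (default FWHM 10 mm; sigma = FWHM / (2·√(2·ln 2))) and divided
by its masked mean ("global-uptake" normalization), giving unit whole-brain
mean. Smoothing is a mask-renormalized convolution —
`smooth(data·mask) / smooth(mask)` inside the mask — so weight that a plain
zero-padded kernel would spill onto background is redistributed onto brain
voxels. This preserves constants exactly and the masked mean to ≤ 0.5 %
relative error (property-tested); because of that small mean drift,
smoothing and global scaling commute only up to ~0.5 % directly, and
exactly once the pipeline ends with the global scaling step (the order used
here is smooth → scale, fixed in the run config). Whole-brain mean was
chosen as the normalization reference; a cerebellar reference is not
implemented. Anisotropic voxels are handled with per-axis sigmas. Brain
extraction and nonlinear template registration are out of scope: synthetic
data are generated on a common grid.

## Metabolic patterns (SSM/PCA) and topographic profile rating

The scaled subprofile model takes the natural log of each masked scan
(intensities are floored at 1e-6 at generation time so the log is always
defined; a non-positive in-mask voxel raises rather than being clamped),
row-centers each subject (removing the multiplicative global factor, which
is additive in log space) and column-centers the group (the removed column
means are the group mean profile, GMP). PCA of the residual (SRP) matrix is
computed by SVD in subject space — efficient since voxels ≫ subjects — with
voxel loadings taken from the right singular vectors.

A pattern is derived from a disease group and a control group: candidate
components are the leading ones jointly explaining ≥ `var_threshold`
(default 0.5) of SRP variance; the default selects the single candidate
whose subject scores best separate the groups by Welch t statistic, with an
optional logistic-regression combination of all candidates. The sign is
fixed so the designated positive group (the disease group, or the controls
for the normal/default-mode stand-in pattern) has the higher mean score.
The GMP and the control-group score mean/SD (SD with ddof = 1) are stored
with the pattern, so a single new scan can be scored prospectively:
topographic profile rating is the dot product of the scan's own residual
profile (log vector − its mean − stored GMP) with the pattern weights,
Z-transformed against the stored control statistics. Scores are invariant
to global rescaling of the input by construction. Choosing natural log
rather than log10 only rescales raw scores and is absorbed by the Z
transform; it is fixed for reproducibility. Bootstrap significance testing
of voxel weights is out of scope.

The experiment driver derives ADRP/DLBRP/FTDRP from each disease's
identification subjects versus the NC identification subjects, and a
DMN-like normal pattern from the pooled dementia identification subjects
versus NC with inverted sign (controls express it more). Identification
subjects are flagged as *leakage* and are barred from classifier test sets.

## ROI uptake features

The second feature set is the mean intensity of every atlas parcel
(restricted to the brain mask) on the globally scaled scans — SUVR-like
uptake ratios. Composite ROIs (e.g. pooling bilateral structures) extend
the label table without touching the label grid; their means are
voxel-count-weighted means of the member parcels. Real parcellations can be
supplied as NIfTI label volumes + TSV tables; the bundled toy atlas is the
test fixture.

## Classifier

A multi-class maximum-margin linear model in one-vs-one error-correcting
output codes: one binary linear SVM per unordered class pair (K = 4 gives
6 learners; the binary learners are scikit-learn `SVC(kernel="linear")`,
the coding, decoding and ensembling are implemented here). Prediction
decodes by loss-weighted voting — argmin over classes of the mean binary
hinge loss `max(0, 1 − m·s)/2` over the learners the class participates
in — with one-vs-all coding available behind config. Regularization is
fixed at C = 1 (no tuning is performed, deliberately), and features are
z-scored with statistics of each training fold only, so application to the
fold's test subjects is strictly prospective.

The ensemble retrains over `n_iterations` (default 500; the demo config
uses 100) stratified resamples: per class, round-half-to-even of 0.7·n
subjects train (leakage subjects forced into training first, quota adjusted
by one if a class would otherwise never be tested) and the rest test.
Iteration *i* uses the RNG seeded `(master_seed, i)`, making the entire
split sequence reproducible from one integer. A subject's final label is
its modal predicted label over its test appearances; ties break by vote
fraction, then by the fixed order AD < DLB < FTD < NC (the tie-break had to
be invented; it is deterministic and documented). Per-subject vote
fractions sum to one and serve as the one-vs-all ROC scores — using the
mean decoded margin instead is a config-level alternative; vote fractions
were chosen because they are bounded, comparable across runs, and already
part of the majority-vote output.

With the default leakage counts (20, 20, 10, 29) out of (63, 79, 23, 41),
127 subjects (43, 59, 13, 12) remain eligible for final labels — the
"reduced" evaluation. For a like-for-like comparison the pattern-based and
ROI-based classifiers share the same split-scheme seed, and the ROI
classifier is additionally evaluated with the same leakage exclusions.

## Metrics

One-vs-all per class: specificity TN/(TN+FP), precision TP/(TP+FP),
sensitivity TP/(TP+FN), F1 = 2PS/(P+S) (0 when P+S = 0, with a logged
warning on any 0/0); overall accuracy is trace/total. Predictions outside
the class set ("other"/inconclusive reader calls) occupy extra
confusion-matrix columns: they count in totals and can never be correct.
Percentages round half away from zero. AUC uses the rank (Mann-Whitney)
formulation with average ranks, so ties contribute 1/2; it is verified in
the tests against exhaustive pair counting.

## Explanation

**NCA.** Per-feature weights maximize the soft leave-one-out
nearest-neighbor objective: weighted distances d(i,j) = Σ_r w_r²·|x_ir −
x_jr|, reference probabilities softmax(−d) over j ≠ i (row-min shifting
guards the exponentials), objective mean_i p_i − λ·Σ w_r², maximized by
L-BFGS from the all-ones start (max 400 iterations, gradient tolerance
1e-6) with the analytic gradient (finite-difference-verified in tests).
The objective depends on w only through w², so weights are reported as
absolute values. λ is selected by cross-validated 1-NN loss in the weighted
metric (ties to the smaller λ). Selection frequency marks, per training
resample, features whose weight exceeds 0.3 × the maximum weight (the 0.3
cutoff on standardized features is adopted as the default), and the
F1-versus-top-k curve re-runs the full ensemble on the k top-ranked
features with the *same* split seeds so k = all reproduces the full model
exactly.

**Shapley values.** The explanation target is the per-class decoded score;
because the multi-class score actually explained is a design choice, the
package uses the *linear* per-class margin (mean of signed learner
margins), for which the marginal-expectation Shapley value has the closed
form φ_j = w_j^(class)·(x_j − reference_j), with the efficiency identity
exact. For arbitrary score functions a Monte-Carlo estimator averages
marginal contributions over random feature orderings (an unbiased sampling
of the same subset-weighted Shapley sum, with per-feature Monte-Carlo SEs);
absent features are imputed from a background sample — independently, or
via the Gaussian conditional on the present features (background mean and
covariance, ridge-regularized with a logged warning when singular) when
feature dependence should be respected. The background/reference set is the
training split of the same resample. Class importance maps are the group
mean of |φ| over all (run, training-subject) entries with that true class,
painted onto the atlas parcels; the experiment driver budgets 50 resamples
by default (config-exposed) and uses the exact linear attribution, so the
budget is cheap. The CLI's `explain` command exposes the NCA weights and
the linear Shapley maps; the sampling estimator (independent/dependent) is
a library-level facility.

## Synthetic cohorts

The generator plants the ground truth the pipeline must recover. A toy
atlas is a Voronoi tessellation of an ellipsoidal mask (semi-axes 42 % of
each grid extent) around randomly drawn interior seeds: cells are convex,
hence connected, non-empty, and partition the mask exactly. Each subject's
volume is

    baseline(x) · roi_multiplier(x) · global_scale + voxel_noise(x)

with a smooth radial baseline (1.0–1.4, higher centrally, so smoothing and
global scaling interact non-trivially), class-specific ROI multipliers
1 − fraction + N(0, variability) in the affected parcels (NC is
effect-free), a log-normal global factor (log-SD `global_scale_sd`, keeping
intensities positive for the log transform) and iid Gaussian voxel noise,
floored at 1e-6.

Default study conditions: 63/79/23/41 subjects per class (206 scans) on a
24³ grid of 2 mm voxels with 8 parcels; each dementia class hypometabolizes
a disjoint parcel pair by 25 % (between-subject SD 5 %); global-scale
log-SD 0.15; voxel noise SD 0.05 (≈ 4 % of baseline). These effect sizes
are in the range of the regional reductions reported for moderate dementia
and give clearly separable but noisy classes. Test fixtures use scaled-down
cohorts (16³ grids, 8–20 subjects per class, 10–100 resamples) so the full
suite and the acceptance script each run in well under a minute of compute
per stage; the problem sizes are stated in the tests themselves.

What the generator does *not* emulate: scanner physics (PSF, attenuation,
partial volume), anatomical MNI-space realism, age/sex covariates, or
correlated multi-region disease topographies. Passing tests therefore
demonstrate that the algorithms recover effects of the planted form —
piecewise-constant regional hypometabolism under global scaling and white
noise — not clinical performance on real scans.

## Numerical conventions and degenerate inputs

- Sample SDs use ddof = 1 (pattern Z reference, Shapley SEs).
- Stratified train quota: Python banker's rounding on 0.7·n, then clamped
  to [max(1, n_leakage), n − 1 when testable].
- Argmin/argmax ties resolve to the earlier index; class order is
  AD < DLB < FTD < NC everywhere.
- Zero-FWHM smoothing is the identity; negative FWHM, non-positive masked
  means, empty masks, single-subject centering, single-class training sets
  and empty λ grids raise with descriptive messages rather than degrading.
- Run manifests checksum the in-memory arrays/tables (SHA-256 of raw bytes
  or CSV text), so reruns of the same config are verifiable bit-for-bit
  independent of container timestamps; cohort volumes written by the CLI
  use uncompressed `.nii` for the same reason.

## Known limitations

- The published derivations of the real ADRP/DLBRP/FTDRP/DMN patterns are
  not reproduced verbatim (component choices and thresholds of the original
  studies are not public); the derivation here is a documented default.
- The linear-margin Shapley target is one of several reasonable multi-class
  scores; rankings can differ under the hinge-decoded score.
- The published performance tables also contain one arithmetically
  inconsistent accuracy figure and one inconsistent
  precision/sensitivity/F1 triple; the metric functions reproduce the
  arithmetic, not the misprints (the test suite flags both).
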