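# Methods

This note documents the models, statistical procedures, numerical choices
and synthetic-data assumptions behind `race_rsa`, including the places
where the design was genuinely open and what the package chose.

## Representational similarity

A layer's representation of a stimulus set is summarised by the Pearson
correlation between the flattened feature vectors of every image pair.
Flattening is row-major; any consistent order gives the same correlations,
so this is a documented convention rather than a modelling choice.
Activations are used exactly as supplied — the module applies no
nonlinearity, so callers decide whether they mean pre- or post-activation
tensors. Correlations are computed in double precision; the diagonal is
forced to exactly 1 and the matrix symmetrised to remove last-bit
asymmetry, so downstream code can rely on `values[i, i] == 1.0`. A
zero-variance feature row is an error naming the offending image (its
correlation is undefined), not a silent NaN.

## Decoding by signal detection

Race decoding is one-versus-rest on class-mean correlations: image *i*'s
score for target race *T* is its mean correlation to the members of *T*,
excluding *i* itself when *i* ∈ *T*. With target images as positives, the
ROC area is computed in its Mann–Whitney form (ties count ½ — the standard
convention; implemented via midranks so it vectorises over permutation
columns), and sensitivity is d′ = √2 Φ⁻¹(AUC).

*Clipping.* AUC ∈ {0, 1} maps to infinite d′. Before the quantile, AUC is
clipped to [ε, 1 − ε] with ε = 1/(2·P·N) (P, N the class sizes — half the
resolution of the AUC grid), or 1e−6 when class sizes are unknown. This
keeps permutation statistics finite while preserving the ordering of all
attainable AUC values; d′ remains exactly 0 at chance and antisymmetric
about it.

*Finite-sample caveat.* The class-mean score is not exactly exchangeable
between classes on strongly block-structured similarity: positives average
P − 1 entries whose conditional distribution differs from the N entries
negatives average, so the shuffled-label expectation of AUC sits slightly
below ½ at small n (≈0.03 low at 12 images). On unstructured similarity
the null AUC is centred at ½. The permutation test is unaffected — it
compares the observed statistic to the same statistic under permutation —
but raw AUCs from very small structured samples should not be read as
bias-free chance deviations.

## Maximum-statistic permutation test

To compare decoding against chance while controlling the familywise error
rate over network layers, class labels are permuted *identically across
all layers* within each permutation (required for a valid maximum-statistic
null), d′ recomputed per layer, and the maximum across layers recorded.
The one-tailed p-value per layer uses the add-one estimator
p = (1 + #{null max ≥ observed}) / (n_perm + 1), with "≥" for exceedances.
The add-one form avoids p = 0 and is a valid p-value under exchangeability;
at 10 000 permutations it differs negligibly from the plain proportion.
Race permutations shuffle the image race labels; identity permutations
shuffle the same/different flags over the 90 pairs of one matching task.
P-values are then Bonferroni-corrected over the three races tested. All
permutation draws come from one `numpy` `default_rng(seed)`, so results are
bit-for-bit reproducible given the seed.

Calibration: with 16 layers of pure-noise features, the familywise
false-positive rate at α = 0.05 lands in [0.03, 0.07] over 500 simulated
datasets (the acceptance suite measures this with 499 permutations per
dataset; the simulation uses 36 images × 40 features per layer — sizes
chosen so the calibration experiment is cheap while leaving the test
statistic non-degenerate).

## Parametric contrasts

Per-image "within > between race" values are the mean correlation to
own-race images (self excluded) minus the mean to other-race images.
Layer × race cells are tested with one-tailed t-tests (paired for
within>between, independent-samples for same>different identity) and
corrected with the Bonferroni–Holm step-down procedure, with monotonicity
enforced (adjusted p's are non-decreasing in raw p order and capped at 1;
delegated to `statsmodels`, verified in tests against a step-down
enumeration oracle). Cohen's d is mean(a−b)/sd(a−b) for paired samples and
the pooled-SD standardised difference otherwise; identical samples give
d = 0, while a zero-SD non-zero difference is an error (the statistic is
undefined). Mixed-design ANOVAs (sphericity corrections, η² effect sizes)
are deliberately not reimplemented: the package emits tidy per-cell tables
that any standard ANOVA routine consumes.

## Behaviour RSA

Behavioural similarity for a matching task is the proportion of "same"
responses per trial across participants (every participant must judge every
trial — incomplete tables are an error listing the missing trials). Each
layer's pair correlations are Pearson-correlated with these proportions.
Significance uses a one-tailed critical r (positive correlation expected,
matching the single-threshold convention of layer-profile plots):
r_crit = t_{1−α,ν} / √(t²_{1−α,ν} + ν) with ν = n_pairs − 2.

Fisher's z-transform clamps |r| to 1 − 1e−7 before atanh so noiseless
r = ±1 cases stay finite. The Fisher z comparison of two correlations uses
the independent-samples form z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)) with a two-tailed normal p. When the two correlations share
trials or participants this test is approximate (the package implements
the independent form and leaves dependency corrections to the caller).

## ROI flood fill

ROIs are grown from the peak voxel of a z map (ties broken by lowest
linear index, so peak finding is deterministic). Growth is greedy: among
the suprathreshold (z > z_min, default 2.3) face-connected neighbours of
the current region, the highest-z voxel is added next, until the target
size (default 500) is reached or the frontier empties. Face (6-neighbour)
connectivity is the default, with 18 and 26 available; the growth order
and connectivity are configuration because "flood fill" alone does not pin
them down. If fewer than the target are reachable, the ROI is the largest
multiple of 100 (interpreting "largest size to the nearest 100" as
rounding down, consistent with published 200-voxel ROIs), dropping the
last-added voxels — which keeps the region connected, since every accepted
voxel neighbours an earlier one. Voxel indices are 0-based; world mm
coordinates come from the NIfTI affine.

## LOPO MVPA and adaptation

For MVPA, parameter estimates are normalised by subtracting, per voxel and
participant, the mean across the analysed (different-identity) conditions.
Each participant's pattern for condition *i* is correlated with the
unweighted voxelwise mean pattern for condition *j* over the *remaining*
participants of their group — the left-out participant never contributes
to their own template. Correlations are computed per ordered condition
pair and averaged on the Fisher-z scale (the alternative — concatenating
patterns before correlating — is a documented variant the package does not
use). Contrasts: same-race = mean z over diagonal face pairs, different
race = mean z over ordered cross-race pairs; the own-race interaction is
(own-race z − other-race z) averaged over participant groups, with
one-tailed paired t and Cohen's d per group; the category contrast
compares cross-race face–face z with face–object z.

Adaptation is a response magnitude, not a pattern, so it uses
*unnormalised* responses: the mean parameter estimate over ROI voxels for
the Different-Identity arrangement minus the Same-Identity arrangement
(positive = repetition suppression). "Peak response" is operationalised as
this ROI-mean beta — block-level GLM estimates carry no within-block time
course from which a literal temporal peak could be taken.

## Synthetic generators

The generators produce data at the level the analyses consume (features
and parameter estimates), not images or BOLD time series.

*Features.* An image of identity *k*, race *r* at layer *l* is
`race_signal[l] · m_r · μ_r + identity_signal[l] · μ_k + σ · ε`, with race
and identity prototypes drawn once per layer from a standard normal and
isotropic Gaussian noise (σ = 1 by default) — the simplest structure that
exercises every analysis. Defaults reproduce the stimulus-set geometry:
3 races × 90 identities × 2 images = 540 images, 16 layers, 90 trials per
race (45 same + 45 different identity). Two images per identity is the
minimum that defines same-identity pairs. The default signal profiles are
logistic ramps over layer index (race rising through the later
convolutional stages, identity in the fully connected stages), and the
White multiplier m = 1.3 plants the own-training-distribution advantage
face networks show; feature dimensionality defaults to 200 per layer.

*Behaviour.* P(same) = g + (1 − 2g)·logistic(β·(r − r̄)) with guess rate
g = 0.1 and slope β = 8 by default; judgements are i.i.d. across
participants.

*Voxel patterns.* Race templates share variance ρ_between (default 0.25)
of a common face component inside total template variance ρ_within
(default 0.5), so cross-race template correlation is ρ_between/ρ_within;
the object template is independent. Participant patterns are
`(1 + δ·own_race)·T_c + baseline + noise` (δ = 0.2, noise SD 0.3 by
default, 28 + 29 participants matching the study sample), with
Same-arrangement responses lowered by the planted adaptation effect
(default 0.4).

What the generators do **not** emulate: spatial voxel autocorrelation,
participant-level response-gain differences, heteroscedastic or
non-Gaussian feature statistics, and any image-level confounds between
races. Passing recovery tests therefore shows the estimators are correct
and calibrated under the assumed structure, not that real data satisfy
that structure.

## Scaled-down experiment sizes

Simulation-based tests run at reduced sizes chosen to keep the suite fast
while leaving every effect estimable: FWER calibration at 6 identities/race
× 40 features × 16 layers, 499 permutations, 500 datasets; decoding
recovery at 10 identities/race × 80 features with a linearly increasing
race-signal profile, 50 seeds; MVPA recovery at 12 participants/group ×
200 voxels, 100 seeds; adaptation recovery at 28/group × 300 voxels,
100 seeds. The acceptance script reports decoding at the full 540-image
geometry (it is cheap at 200 features).

## Conventions and limitations

- CLI exit codes: 0 ok, 2 usage error (click's convention), 1 data or
  configuration error.
- Result tables are written as plain CSV with fixed column names; a
  manifest (config + SHA-256 + package version) suffices to regenerate any
  output.
- Permutation p-values are never 0 by construction; the smallest attainable
  value is 1/(n_perm + 1).
- The Fisher z comparison assumes independent samples (see above).
- Decoding is correlation-score + ROC by design; no trained classifiers.
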