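# Methods

This note documents the models implemented in `painscope`, the generative
model behind the synthetic corpus, the numerical choices that matter, and
what the test suite does and does not establish about real data.

## 1. The decoding model

Each trial (after preprocessing, a participant × rating-quartile average) is
a vector over the in-mask voxels.  The decoder is principal component
regression (PCR): column-center the training matrix `X` (no column scaling —
images are already row-standardized, and column scaling would re-weight
voxels), take the SVD `X_c = U S Vᵀ`, regress the ratings on the first `k`
component scores by OLS, and back-project:

    w = V[:, :k] · diag(1/s)[:k] · U[:, :k]ᵀ y,    ŷ(x) = (x − x̄)·w + ȳ

Because the component scores are orthogonal with norms `s_j`, the
coefficient of component `j` is `(u_j·y)/s_j` independently of `k`, so one
SVD of a training split yields validation predictions for every `k` at once.
This makes the exhaustive scan of the dimension the cheapest strategy, and
it is the default; a Gaussian-process Bayesian optimizer
(expected-improvement acquisition over the integer range, 30 evaluations) is
available for settings where per-`k` evaluation is genuinely expensive, and
is tested to land within 5% of the grid minimum MSE.

`k` ranges over `[1, R]` with `R` the numerical rank
(`s > max(n,p)·eps·s₁`); intercept-only models (`k = 0`) are precluded.
**Parsimony rule:** among dimensions whose inner-CV MSE is within 1%
(relative) of the minimum, the smallest is chosen.  The MSE curve is
typically flat past the optimum and the argmin otherwise wanders tens of
components into the tail, where the extra dimensions only add estimation
noise to the predictions.

## 2. Model spaces and selection

Six voxel-set hypotheses are built from a parcellation: three modular spaces
whose candidates are the parcels at one scale (elementary regions, fine
resting-state networks, coarse networks), and three fixed spaces (the union
of nociceptive-pathway regions, a meta-analytic mask covering ≈ 30% of the
brain, and the full mask).  Real atlases need not nest across scales and the
code never assumes nesting; the synthetic parcellations do nest exactly.

For modular spaces the module is a hyperparameter: every candidate is
evaluated by inner-CV MSE, each candidate fit running its own innermost
dimension optimization (three nesting levels in total).  Ties break toward
fewer voxels, then label order.  The innermost level uses 3 folds (it
estimates a single integer hyperparameter; the inner and outer levels use
5).

## 3. Cross-validation and performance

The outer scheme is 2×5 repeated k-fold: participants are shuffled within
study and dealt round-robin to folds (random per-study starting fold), so no
participant is split across folds and per-fold study counts differ by at
most one.  Repeats use distinct derived sub-seeds.  Performance is the
within-participant Pearson correlation between cross-validated predictions
(averaged over the two repeats) and observed ratings, Fisher-z transformed
with |r| clipped at 1 − 10⁻⁶ (four quartile points can produce |r| = 1).
Participants with degenerate predictions are recorded as missing and
logged.

Two drivers: the *multistudy* analysis samples an equal number of
participants from every study (the smallest study's size, default cap 16)
before pooling and training one learner; the *study-wise* analysis retrains
the same learner independently per study and pools the predictions,
estimating how the training procedure generalizes rather than how one fitted
model performs.

## 4. Mixed-effects comparisons

Per-space performance is compared with a variance-components linear mixed
model fit by REML:

    z ~ 1 + C1..C5 + (1|participant) + (1|study) + (C1..C5|study)

with independent (diagonal) variance components.  The orthogonal planned
contrasts over (REGION, FRSN, CRSN, PATHWAYS, META, FULL) are:
C1 distributed − modular; C2 region − networks; C3 cRSN − fRSN; C4 meta −
pathways; C5 full − multisystem.  Design columns are scaled by `1/‖c‖²` so
each coefficient estimates its named difference directly.  The
non-orthogonal FULL − REGION comparison is fitted separately on the two
spaces involved.

Implementation notes:

* The engine computes all likelihood quantities from per-block sufficient
  statistics (blocks = connected components of the grouping structure) via
  the Woodbury identity, so an evaluation costs O(Σ q_b³) independent of the
  number of rows.  Estimates agree with `statsmodels.MixedLM` to ≥ 4
  decimals on shared models.
* Degrees of freedom are Satterthwaite: `df = 2 f²/(∇f' H⁻¹ ∇f)` with
  `f(φ) = c'(X'Σ(φ)⁻¹X)⁻¹c`, the gradient by central differences in the
  variance parameters φ and `H` the observed information of the REML
  criterion.  Agrees with `lmerTest` to 2% on shared models (tested via
  Rscript).
* Random study slopes require more study levels than slope terms to be
  identifiable; with too few studies the model drops to random intercepts
  and flags the reduction.  A convergence-failure ladder does the same.
* Bayes factors for non-significant contrasts use the BIC approximation on
  ML refits with and without the contrast's fixed effect (random structure
  unchanged); BF01 > 10 is reported as a confirmed null.
* Per-module screening fits `observed ~ predicted` with random participant
  and study intercepts and slopes, thresholded at the Šidák level
  `1 − (1−α)^{1/m}` over the `m` modules of one scale.

**Calibration check.**  The predictive interval for a new study's mean z in
space *s* is `x_s'β̂ ± t_df·√(x_s'Ĉx_s + σ̂²_study + Σ_j σ̂²_j d_j(s)² +
(σ̂²_participant + σ̂²)/n_p)`.  The last term — the sampling noise of a
finite-participant study mean — is included beyond the study-level variance
because the observed holdout quantity is a sample mean, not the latent study
effect; omitting it measurably under-covers.

## 5. Weight-map stability

Bootstrap unit is the participant (cluster bootstrap; resampling trials
would break the repeated-measures structure).  `k` is frozen at the
full-data optimum during resampling to isolate weight variability from
hyperparameter variability; if a resample's rank drops below `k` the
dimension is clipped.  Voxelwise z = bootstrap mean / bootstrap SD, p from
the normal tail, thresholded at α = 0.05 uncorrected (default 5008
resamples).  Fold maps from modular spaces are conjoined as the union of
significance masks, with mean-of-significant weights and a flag for voxels
where folds disagree in sign.  Cross-scale similarity is the Pearson
correlation of weights over the intersection of masks (reported missing
below 10 voxels), with an optional permutation p.  The region-coverage test
compares each region's fraction of significant voxels to shuffles of the
mask over all in-mask voxels, `p = (1 + #{null ≥ obs})/(n_perm + 1)`.

The bootstrap z is well calibrated under a pure-noise null when `k` is an
appreciable fraction of the sample rank; at very small `k` the resampled PC
subspace is unstable on noise and the normal approximation turns
conservative (fractions below nominal).  The calibration test therefore
runs in the stable regime (V = 800, 96 rows, k = 45).

## 6. Mediation

All variables (factors standardized, mediator = decoder predictions,
outcome = ratings) are stripped of participant fixed effects by
within-participant demeaning.  Path a regresses the mediator on all factors
jointly; path b/τ regresses the outcome on mediator plus all factors.  The
indirect effect per factor is α_f·β; `total = τ + α·β` holds exactly for
least-squares paths on the same rows (asserted to 10⁻¹⁰).  Uncertainty is a
participant-level bootstrap (default 5000) with bias-corrected percentile
intervals (no acceleration constant).  Residual df for partial r² and SEs is
`n − participants − parameters`.  Percent mediated =
`100·indirect/(indirect + direct)`, rounded; reported missing when the total
is ≈ 0.  A wedge table decomposes the outcome-model R² over mediator and
factors by ordering-averaged increments (below).

## 7. Behavioral model

Backward stepwise selection of linear main effects with participant fixed
effects always retained (absorbed by demeaning, with df corrected);
collinear factors are dropped before stepping.  Variance wedges: the
participant block enters first and takes its R² increment; the remaining
factors share the rest by Shapley/LMG attribution — the average R² increment
over all orderings, computed by subset enumeration (≤ 14 predictors).  The
attribution is order-invariant, nonnegative, and sums exactly to the model
R².

## 8. Specificity

Frozen decoders score per-participant task-contrast maps standardized like
training images (per-image mean 0/SD 1, so constant offsets are removed).
Planned contrasts — pain − non-pain, heat − other pain modalities, and the
(distributed − local model) × (pain − non-pain) interaction — are tested
with random participant *and task* intercepts: scores cluster by task
because each task evokes its own pattern shared by its participants, and
without the task term the null case is anti-conservative.  For the
interaction, scores are standardized within model first: different decoders
have arbitrarily different weight scales, so discrimination must be compared
in each model's own score units.  The optimal cut point minimizes
|sensitivity − specificity| over midpoints of sorted unique scores (ties →
maximal sensitivity + specificity); Youden-style alternatives can be read
off the reported sensitivities.

## 9. The synthetic corpus

The generator's default layout mirrors a seven-study thermal-pain archive
plus four validation studies: per-study participant counts (28, 17, 16, 29,
26, 30, 25; validation 33, 45, 40, 87), trials per participant (81, 64, 70,
64, 48, 16, 96; 97, 48, 60, 36), stimulus temperatures between 41.1 and
50 °C (discrete levels or a continuous range per study), and per-study
manipulation sets (predictive cues, perceived control, social context).
Ratings follow

    rating = Σ_f b_f·x_f + u_participant + ε_brain + ε_report

with standardized regressors, cue regressors drawn independently of
temperature, habituation linear in trial index, participant intercept SD
0.8, and two noise terms: ε_brain (SD 0.35) is encoded in the images,
ε_report (SD 1.0) is report noise no decoder can reach — a common
performance ceiling.  Defaults put the factor coefficients at 0.2–0.3 in
balanced proportion; per-study overrides are supported.

Images are

    image = Σ_f b_f·x_f·pattern_f + ε_brain·pattern_pain
            + global-mode noise + parcel noise + white noise + study offset

scaled per study by `1 + N(0, 0.1)`.  Patterns are unit-norm random fields
(amplitude 7) confined to the scenario's signal regions:

* **LOCAL** — every channel lives in one region;
* **MULTISYSTEM** — the factor channels are dealt round-robin to the
  nociceptive-pathway regions (≥ 3 regions across ≥ 2 coarse networks), so
  *different influences on pain live in different systems*; the
  pain/unique-variance channel spans half of the signal regions, stratified
  across coarse networks, so no single module covers most of it;
* **GLOBAL** — the same dealing over at least half of all regions.

This channel segregation is what makes spatial scope matter: at the
rating-quartile level every regressor's bin mean is (by selection) nearly
proportional to the bin rating, so if one region carried all channels it
would be a near-perfect proxy for the decodable signal and no scale
difference could exist.

**Noise model.**  Voxel noise splits into a few global spatial modes
(motion/physiology-like, 85% of variance, shared across studies), a
parcel-shared residual (5%), and voxel white noise (10%).  An earlier
two-component version (parcel factor + white only) planted exactly R
high-variance noise directions orthogonal to all signal, which made
full-brain PCR strictly worse than any small-space decoder — contradicting
the intended LOCAL equivalence of full-brain and best-region decoding and
the empirical behavior of real multi-study corpora, where noise is dominated
by a few global components.  The amplitudes are calibrated so that signal
eigenvalues sit clearly above the white-noise bulk edge (so full-brain PCA
resolves them) and decoding accuracies land at moderate within-participant
correlations rather than at the Fisher-z ceiling.

A salience/arousal channel (global pattern, partially rating-correlated
drive) is implemented but off by default: with it enabled, every space gains
the same nonspecific decodable component and planted scale differences
shrink.

**Specificity maps.**  Eighteen tasks (6 pain across heat/mechanical/
visceral, 6 cognitive-demand, 6 aversive), 15 participants each.  Pain-task
maps contain the planted pain pattern and a modality component, both scaled
by the modality amplitude (heat 1.0 > mechanical 0.7 > visceral 0.6); all
maps share a salience pattern with per-map arousal jitter and a
task-specific pattern, plus white noise at the trial-averaged scale.  With
pain amplitude 0, pain and non-pain maps are exchangeable.

**What passing tests show.**  The generator reproduces the *statistical
structure* the analysis assumes — factor designs, participant/study
hierarchy, quartile averaging, planted spatial scope — not the spatial
autocorrelation, inter-subject anatomical variability, preprocessing
artifacts or non-linearities of real fMRI.  Green scope-recovery tests mean
the pipeline can tell distributed from local signal under these idealized
conditions; they do not guarantee sensitivity on any particular real
dataset.

## 10. Problem sizes used in tests

Simulation-based tests run at a reduced scale chosen to keep the full suite
around ten minutes on one core: scope recovery uses 3 studies × 30
participants × 16 trials on a 1000-voxel grid with 20 regions (8 fRSN, 4
cRSN, 6 pathway regions) over 20 generator seeds; mixed-model calibration
uses 500 simulated null performance tables (8 studies × 12 participants) and
200 holdout coverage draws; mediation coverage uses 200 simulations at 40
participants with 1000 bootstrap resamples (scaled down from 5000); weight
bootstrap calibration uses 1000 resamples (scaled down from 5008).  The
acceptance script (`scripts/acceptance.py`) re-runs the pipeline at the
3-study desk scale with one extra validation study.

## 11. Known limitations

* Sensitization/habituation is a single linear term per participant; no
  site-specific split.
* No multilevel random-slope mediation (participant fixed effects instead);
  single mediator only.
* The BIC Bayes-factor approximation is crude at small study counts.
* The bootstrap weight-map normal approximation is conservative at small k
  (see §5).
* Real atlases are consumed as label images + tables; no registration
  beyond nearest-neighbor reslicing is provided, and meta-analytic maps are
  binarized at > 0.
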