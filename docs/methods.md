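# Methods

This document is the scientific account of every procedure implemented in
`statecue`: the models, their estimation, the inferential machinery, and
the design of the synthetic validation cohort.  Vocabulary: a *TR* is one
sample of the fMRI series (1 s by default); a *parcel* is a cortical
region whose voxels have been averaged (100 parcels grouped into 17
functional networks); *fractional occupancy* (FO) is the proportion of
TRs within an interval assigned to a state.

## 1. Preprocessing

Each subject/run parcel series (T × P) is z-scored per parcel
(`hmm.standardize`, sample SD); constant parcels are an error, reported by
column index.  Standardized series from all subjects are concatenated and
reduced by principal component analysis (`hmm.pca_fit`), keeping either
the smallest dimension reaching a cumulative explained-variance threshold
(default 0.9) or a fixed component count.  The projection is estimated
once on the data entering model fitting and reused for any data decoded
later — decoding never refits the projection.

## 2. Gaussian hidden Markov model

Brain states are modeled as K latent states with first-order Markov
dynamics, each emitting a full-covariance Gaussian in PC space.
Estimation (`hmm.hmm_fit`) is maximum likelihood via
expectation–maximization (Baum–Welch):

- **E-step** — scaled forward–backward recursions.  Concatenated
  subjects/runs are independent chains: the recursion restarts with the
  initial distribution at every sequence boundary, and transition
  statistics never cross boundaries.  Equal-length sequences are processed
  in a single batched recursion (identical arithmetic, vectorized across
  chains).
- **M-step** — closed-form updates of the initial distribution, row-
  stochastic transition matrix, state means, and covariances, with a small
  diagonal ridge (1e−6) for numerical positive-definiteness.  A state
  whose expected occupancy falls below one frame is reseeded on a random
  frame, preventing silent state collapse.
- **Initialization** — k-means centers for the means, within-cluster
  scatter for the covariances, 0.9 self-transition, uniform initial
  distribution.  EM is restarted from multiple k-means seeds (default 5)
  and the restart with the best final log-likelihood is kept.  Convergence
  is declared when the per-frame log-likelihood gain falls below `tol`.

Decoding (`hmm.hmm_decode`) returns both posterior state probabilities
(forward–backward) and the single best path (log-space Viterbi).  The
forward log-likelihood and the posteriors are verified in the test suite
against brute-force enumeration of all K^T paths on small problems, and
against an independent HMM implementation (hmmlearn) on larger ones.

## 3. Choosing K: split-half stability

`brainstate.k_selection` chooses the number of states by reproducibility
rather than fit.  For each candidate K and each repeat, subjects are
randomly split into halves; each half gets its own HMM (shared PCA space,
estimated on the full sample so both halves live in identical
coordinates); both models decode the *first* half, and the two labelings
are compared with three complementary metrics:

- **zRand** — the pair-counting Rand coefficient z-scored against its
  exact permutation null.  The null mean and variance are computed
  analytically from the hypergeometric distribution of pair overlaps;
  the implementation is validated against a 10,000-shuffle empirical
  oracle.  Degenerate (single-cluster) labelings are flagged NaN.
- **NMI** — normalized mutual information (arithmetic normalization),
  defined as 0 when either labeling is constant.
- **Concordance** — mean correlation of Hungarian-matched state
  activation maps from the two models (validated against exhaustive K!
  enumeration).

Repeats in which a model degenerates are dropped; fewer than three
surviving repeats is an error.  Metric means are min-max scaled across
the K range and averaged into a composite; the chosen K maximizes the
composite.

**A note on calibration.**  Split-half stability is conservative about
rare states.  When the true dynamics leave one state only briefly
occupied (a few dozen TRs in a 500-TR session), half-samples frequently
disagree on that state, and a merged (K−1)-state solution is genuinely
more reproducible than the true K.  On synthetic cohorts this shows up as
systematic under-selection whenever a slow-mixing state chain produced a
rare state; increasing optimization effort (more repeats, restarts, or EM
iterations) does not change the outcome, because the instability is a
property of the data, not the optimizer.  The acceptance suite includes a
selection-frequency check at the true K that documents this behavior and
is expected to fail for this reason; the companion recovery check (state
maps and paths at the true K) passes with wide margins.

## 4. State profiles

`brainstate.state_profiles` summarizes each state over the TRs assigned
to it: the activation map (mean standardized signal per parcel), the
within-state functional connectivity (Pearson correlation matrix, with an
optional 17-network reduction), and a connectivity contrast of each state
against all others (two-sided t across subjects, Benjamini–Hochberg FDR
per state).  States with fewer than `min_trs` assigned TRs are flagged
empty rather than summarized from noise.

## 5. Continuous appetite ratings

Raters watch the videos and press ordinal keys (1–3) whenever appetite
changes.  `ratings.resample_events` bins the BIDS-style event stream into
TRs (mean pressed value per bin; empty bins are 0 = no press).
`ratings.group_average` z-scores each rater trace and averages them, and
also returns the average convolved with a canonical double-gamma
hemodynamic response function (`ratings.hrf_kernel`, peak 6 s,
undershoot 16 s, unit absolute sum).

Inter-rater reliability (`ratings.split_half_reliability`) repeatedly
splits raters into halves, correlates the half-averages (Spearman), and
applies the Spearman–Brown correction 2r/(1+r).  The observed statistic
is the *mean* corrected coefficient over iterations; the permutation null
reuses each iteration's split with one half circularly time-shifted, and
p is the proportion of null draws exceeding the observed mean (add-one
smoothed).

**A note on calibration.**  Because the observed statistic is a mean over
many random splits while each null draw is a single split, the null
distribution is wider than the sampling distribution of the observed
statistic.  Under truly independent raters the test therefore rejects at
well below the nominal rate (measured ≈ 0.01 at α = 0.05) — it is valid
(never anti-conservative) but conservative.  This is a property of the
procedure as defined, reproduced faithfully here; the acceptance suite's
uniformity band documents it as an expected failure.

## 6. Alignment

`alignment.make_windows` tiles each run with sliding windows (default 5
TRs, step 2; half-open intervals).  For each subject and window,
`alignment.windowed_features` computes the K-vector of fractional
occupancies (hard Viterbi counts, or posterior means with `soft=True`)
and the window-mean group appetite — the feature/target pairs for
prediction.

## 7. Predicting appetite from state occupancy

`prediction.loso_cv` runs leave-one-subject-out cross-validation of ridge
regression from windowed FO to windowed appetite.  All preprocessing is
fitted strictly inside the training fold and applied frozen to the test
subject:

1. confound residualization (age, sex, motion; constant or collinear
   columns dropped), coefficients from training rows only;
2. min–max scaling to the training range (test rows may exceed [0, 1]);
3. ridge with the penalty chosen by an inner K-fold cross-validation over
   a logarithmic grid (1e−3…1e3, 20 points), ties broken toward the
   smaller penalty.

Per-subject performance is the Pearson correlation between predicted and
observed windows of the held-out subject; the *individual* summary is the
mean over subjects, and the *group* summary correlates the pooled
predictions.  `prediction.cross_generalize` applies a model trained on
one video's windows to another video's windows, testing whether the
FO→appetite mapping is stimulus-general.

Feature importance (`prediction.bootstrap_importance`) bootstraps
*subjects* (the exchangeable unit of a cohort design), refits the
group-level ridge per replicate, and summarizes each coefficient by its
bootstrap mean, SD, Z, normal-approximation p, and Benjamini–Hochberg
significance.  The test suite plants known nonzero and zero coefficients
and verifies detection and false-positive rates.

A leakage probe in the acceptance suite perturbs held-out rows arbitrarily
and asserts that every train-fitted preprocessing parameter is unchanged.

## 8. Subject-level associations

- **State expression** (`association.state_expression`) — the correlation
  between one state's windowed FO course and the group appetite target,
  concatenated across runs; a per-subject scalar measuring how tightly
  that subject's state dynamics track group appetite.
- **Partial correlation** — Pearson correlation of OLS residuals with
  t-distributed p (df = n − q − 2); validated against pingouin.
- **Condition comparison** (`association.condition_fo_compare`) — one-way
  repeated-measures ANOVA of state FO across task conditions (subject as
  blocking factor) with BH-corrected pairwise paired t-tests; validated
  against pingouin.
- **Mediation** (`association.mediation_bca`) — the two-path OLS
  decomposition (a: X→M; b: M→Y|X; c: total; c′: direct) with shared
  covariates and a bias-corrected accelerated (BCa) bootstrap interval on
  the indirect effect a·b (bias from the bootstrap CDF at the point
  estimate, acceleration from jackknife skewness).  The identity
  a·b + c′ = c holds to numerical precision by construction and is
  asserted in tests.

**A note on the mediation null.**  Coverage of indirect-effect intervals
depends on which null holds.  Under a *partial* null (one path zero, the
other active) the BCa interval covers near-nominally (measured 0.936 at
the 0.95 level).  Under the *complete* null (both paths zero) the product
a·b concentrates sharply at zero and bootstrap intervals over-cover
(measured 0.994) — a long-documented property of product-of-coefficients
inference, not an implementation artifact.  Calibration checks therefore
use the partial null.

## 9. BMI-trajectory clustering

Six-month BMI series are compared by the Pearson correlation of their
within-subject mean-removed trajectories (vertical offset does not affect
shape), clustered with average-linkage (UPGMA) hierarchical clustering on
1 − r, and cut at k = 2 by default.  Davies–Bouldin and Calinski–Harabasz
curves over candidate k support the choice (lower DB better, higher CH
better).  Constant trajectories are excluded with a warning.  The UPGMA
merge structure is validated against a naive O(n³) reference, and
cluster recovery against planted two-type cohorts.  State expression is
then contrasted between trajectory types with a two-sample t-test.

## 10. Synthetic cohort generator

`synthetic.gen_cohort` builds cohorts with fully planted ground truth;
the generator's defaults define the reference validation cohort
(20 subjects, one 500-TR run, 100 parcels, K = 6 states, 12 raters).

- **States** — each state activates 2–3 of the 17 networks with
  orthogonal, disjoint parcel patterns (pairwise cosine similarity of
  state means ≤ 0.5); emission noise is isotropic with SD 1.0, i.e.
  parcel-level SNR 1 — multivariately well separated but far from
  trivial.
- **Dynamics** — a single group state chain per run (0.9 self-transition,
  uniform off-diagonal); each subject's path is the group path with
  i.i.d. jitter (probability 0.1 of a random relabel per TR), so subjects
  share dynamics imperfectly, as inter-subject correlation designs
  assume.
- **Appetite** — a state-weighted course (moving-average smoothed, scaled
  to [0, 3]) drives ordinal rater key presses through fixed percentile
  cut points plus rater noise.
- **Couplings** — each subject's appetite-tracking gain is planted, and
  BMI is generated from the gain to yield a target gain–BMI correlation
  (default 0.32).  Mediation paths a = b = 0.5, c′ = 0 connect BMI →
  gain → post-scan craving; the latent noise SDs are derived jointly so
  the planted paths and the gain–BMI correlation are mutually consistent.
- **Trajectories** — two 6-month BMI templates (rising ramp vs flat-then-
  falling) with noise SD 0.05 (template separation ≥ 3× noise);
  trajectory type is assigned by a logistic function of the coupling
  gain, giving a between-type gain separation of d ≈ 1.0.
- **Determinism** — every random component draws from its own
  `SeedSequence` substream of the cohort seed, so regenerating any
  component is independent of the others and bitwise reproducible.

## 11. Pipeline and provenance

`pipeline.run_pipeline` executes the stages (ratings → HMM → profiles →
alignment → prediction → importance → expression → mediation →
trajectories) on plain TSV/JSON artifacts, writing `manifest.json` with
the configuration hash, seed, per-stage timings, and SHA-256 checksums of
every artifact.  Any stage can be rerun standalone from prior artifacts;
a missing upstream artifact raises an error naming the stage to run
first.  Reruns with the same configuration and seed reproduce every
artifact bitwise; this is asserted in the acceptance suite.
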