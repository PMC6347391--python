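# Methods

## Problem and approach

Late-stage knee osteoarthritis (OA) alters gait, and whether total knee
replacement restores healthy joint function is not well captured by
patient-reported scores alone. This package implements an objective,
waveform-level assessment: multi-channel gait curves are reduced to
principal-component (PC) scores, the most discriminatory scores are fused
into a belief that a subject walks with osteoarthritic or non-pathological
(NP) function, and recovery after surgery is tracked as movement of that
belief across a barycentric simplex. Because the motion-capture data behind
the published analysis are not deposited, the package ships a synthetic
cohort generator that reproduces the *statistical structure* of the study's
printed group tables, so every stage is exercised end to end on data with a
known ground truth.

## Waveform conventions

Each subject contributes 23 channels: nine joint rotation angles (hip, knee,
ankle in sagittal, frontal and transverse planes; full gait cycle), nine
joint moments and three ground-reaction-force (GRF) components (stance
phase), and two centre-of-pressure position channels relative to the foot.
The study design enumerates 22 channels unambiguously; the mediolateral COP
channel is our choice for the 23rd and is flagged as an assumption in
`channels.py`. All curves are linearly resampled to 101 points (0–100 % of
phase); endpoints are preserved exactly. GRFs are scaled to fractions of body
weight, `F / (m g)` with `g = 9.81 m/s²` (a `mass` divisor switch covers the
N/kg convention), and moments to percent bodyweight times height,
`100 M / (m g h)`. Ensemble curves are pointwise means of a subject's
time-normalized trials; fewer than three trials is an error, not a warning.
Outlier-trial removal is an explicit upstream exclusion list, never an
automatic detector.

## PC feature extraction

PCA is fit per channel on the pooled pre-operative training cohort
(patients + controls) using the covariance of the centred
subjects-by-samples matrix — no per-sample standardization, since curves
within a channel share units (a `standardize` switch exists). The first
three components per channel give 3 × 23 = 69 candidate features. Two sign
conventions are applied in order: (1) the largest-magnitude entry of each
eigenvector is made positive, removing solver-dependent ambiguity; (2) any
column whose OA training mean exceeds the NP training mean is negated
(eigenvector and scores together, flip recorded), so a low score always
points toward osteoarthritic function. The second step is idempotent and has
no statistical effect downstream. Follow-up data are always projected with
the frozen basis, never refit. Single-component reconstructions
(`mean + score · eigenvector`) with representative extremes at the 5th/95th
score percentiles (configurable) visualize what each component encodes.

## Evidence classifier

The frame of discernment is {OA, NP}. Each feature value `v` is mapped to a
body of evidence (m_OA, m_NP, m_U) via a sigmoid confidence factor

    cf = 1 / (1 + exp(-k (v - θ)))

and a linear, truncated mass construction

    m_OA = max(0, B (cf - A) / (1 - A)),
    m_NP = max(0, B (1 - cf - A) / (1 - A)),
    m_U  = 1 - m_OA - m_NP,

with `A ∈ [0, 0.5)` the confidence level at which a committed mass reaches
zero and `B ∈ (0, 1]` the cap on committed mass (single-feature uncertainty
never falls below `1 - B`). Defaults `A = 0.1`, `B = 0.9`. Bodies of
evidence are fused by Dempster's rule; with `B < 1` every body keeps
positive uncertainty mass, so total conflict (K = 1) cannot arise from
fitted features. A subject is OA when the combined m_OA strictly exceeds
m_NP; exact ties are reported as `unclassified` rather than broken
arbitrarily, because the decision rule is a strict inequality.

Training is deterministic moment matching: per feature, θ is the midpoint of
the class means and |k| = 4 / |class-mean difference|, which places the
confidence factor at 1/(1+e⁻²) ≈ 0.88 at each class mean; the sign of k
makes higher confidence point toward OA (negative under the OA-low score
convention). Features with exactly zero class separation carry no direction
and are dropped. An optional Nelder-Mead refinement of the shared (A, B)
pair minimizes training misclassification plus mean simplex distance to the
own-class vertex; the deterministic path is the default so results are
seed-free.

Feature selection follows a split-half protocol to curb over-fitting:
subjects are split into two class-stratified halves (seeded), every feature
is scored within each half by its single-feature leave-one-out (LOO)
accuracy, and the retained set is the intersection of the two halves' top-N
lists (default N = 18, the count retained at the published design scale; the
pipeline reports the resulting intersection size rather than forcing it).
Features tying with the N-th accuracy are included — accuracies are exact
multiples of 1/n, so ties are exact and the retained set is invariant to
column order. Whether ranking uses LOO or resubstitution accuracy within
halves is an open choice; LOO is used here. For a single feature the LOO
decision reduces to the sign of `k (v - θ)`, which gives an exact fast path
(cross-checked against the general implementation in the tests).

Belief triples are drawn in an equilateral simplex with NP at (0, 0), OA at
(1, 0) and full uncertainty at (1/2, √3/2); the locus B(OA) = B(NP) is the
vertical median x = 1/2 (the decision boundary), and the loci
B(OA) = 0.5 / B(NP) = 0.5 bound the "dominant" regions.

## Statistics

Two contrast families are computed per retained feature: paired pre- vs
post-operative within the surgical group, and unpaired control vs
post-operative. Parametric assumptions are checked with an explicit gate —
Shapiro-Wilk at α = 0.05 on the paired differences, or on each group for the
unpaired contrast; constant samples fail the gate. Gate passed: paired t /
Welch t (unequal variances, since published group variances differ). Gate
failed: Wilcoxon signed-rank / Mann-Whitney U, two-sided. Identical paired
samples short-circuit to p = 1 with a degeneracy flag. Bonferroni adjustment
`min(1, m p)` is applied within each family separately (m = number of
features per family; the published table reports both contrast columns but
never states the family, so separate families are the default and the
choice is configurable); a feature is significant when the adjusted p falls
strictly below α = 0.05. The published abstract and table disagree on which
hip feature carries p = 0.003 vs 0.007, and one table row lacks a
significance mark its footnote implies; the implementation reports exact
adjusted p-values and leaves display thresholds in configuration rather
than resolving that inconsistency.

The 12-item knee outcome score (items 0–4, total 0–48) is split into a
function subscale (items 2, 3, 7, 11, 12; percent of 20) and a pain
subscale (the other seven items; percent of 28), 100 % best.

## Synthetic cohort generator

Per channel, a subject's noise-free ensemble curve is

    curve(t) = mean_curve(t) + Σ_j s_j · mode_j(t),

where the modes are the first three members of an orthonormalized cosine
family over the 101-point grid (smooth, waveform-like, orthonormal by
construction, seed-independent) and channel mean curves are random low-order
cosine series. Walking trials add i.i.d. Gaussian noise (`trial_noise_sd`,
default 1.0 waveform units — with six trials per subject this leaves
ensemble-level score noise of ≈ 0.4 score units, small against the retained
features' SDs of 2–12) and observed ensembles are the trial means, exactly
as the pipeline would compute them.

Scores for the 18 retained (channel, PC) features are drawn from
group-specific Gaussians whose means and SDs are the published
pre-operative, post-operative and control values; entries the source table
prints as median (IQR) are deliberately treated as mean/SD — the generator's
role is structural, not distributional replication. One printed scale value
carries a spurious minus sign and is used as its magnitude. The remaining
51 columns are zero-mean with SDs (9, 5, 1.5) by component index, chosen so
that within every channel the three generating-mode score variances are
strictly descending — the condition under which fitted component order
matches generating-mode order. Paired pre/post scores per patient are
bivariate Gaussian with correlation `paired_correlation` (default 0.5; the
study reports no within-subject correlation, so a mid-range value is used
and it is configurable).

Metadata emulate the published participant characteristics: group-specific
BMI distributions (32.5 ± 6.5 vs 24.3 ± 3.7 kg/m², mass derived via
height ~ 1.70 ± 0.09 m), and knee-score items drawn Binomial(4, p) with
subscale-specific p rescaled so expected totals hit the published group
locations (19.5 pre, 36 post, 48 controls; the printed totals and subscale
percentages are not exactly mutually consistent — the total wins). Controls
score the maximum on every item, matching the published 48.0 (0.0).

What the generator does **not** emulate: real gait curves are not
three-dimensional per channel, trial noise is autocorrelated rather than
white, channels are correlated through shared dynamics, score distributions
are skewed where the source flags non-parametric entries, and clinical
covariates (age, velocity) are absent. Passing tests therefore demonstrate
that the *pipeline machinery* is correct and that the published
classification result follows from the printed group statistics — not that
the method would achieve the same numbers on new patients.

## Numerical choices and degenerate inputs

* Mass triples must be nonnegative and sum to 1 within 1e-10; Dempster
  fusion is validated against a brute-force nine-term enumeration oracle.
* PCA uses SVD of the centred data matrix; zero-variance channels yield zero
  eigenvalues, zero scores and zero variance fractions (guarded against
  0/0 at a relative threshold of 1e-12).
* Identical seeds give bit-identical cohorts and byte-identical pipeline
  artifacts; all randomness descends from one root seed through named
  substreams (cohort draw, ranking split). CSVs are read back with
  round-trip float parsing so the file-based and in-memory paths agree
  exactly.
* GRF/moment normalization rejects non-positive mass or height; ensemble
  averaging rejects mixed subjects/channels/phases.

## Problem sizes used in the checks

The cohort-level checks run at the published design scale (30 + 30 subjects,
23 channels, 18 retained features; the headline LOO result is the median
over 20 generator seeds). The PCA score-recovery check runs on a zero-noise
cohort of 5,000 subjects per group: the sample covariance between mode
scores dilutes the weakest component's recovered-vs-true correlation by
about z²/2n (z standard normal) regardless of how well separated the mode
variances are, so a 0.999 per-component criterion is a statement about
estimation error at large n, not about any implementation at n = 60. Type-I
calibration of the gated unpaired contrast uses 1,000 null replicates at
n = 30 + 30.

## Known limitations

* The mass-construction equations and the training rule are not printed in
  the source study (they live in the classifier's lineage); the standard
  sigmoid/linear-truncation construction and moment-matching fit used here
  are documented choices, and all four parameters per feature are
  serialized with the model.
* The retained-feature count on synthetic cohorts depends on the top-N knob
  and the realized separations; the pipeline reports it rather than forcing
  the published 18.
* Only the two-hypothesis frame is supported; no alternative combination
  rules (Yager, PCR5) and no multi-class extension.
* No inverse dynamics or marker-level processing: the package starts from
  waveforms.
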