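# Methods

## Scope and model

`netgranger` analyses directed interactions between a small number of
resting-state network time courses (default k = 6: anterior/striatal
salience, left/right central-executive, anterior/posterior default-mode)
sampled every 2 s (Nyquist 0.25 Hz). The core model is a vector
autoregression

    Y_t = v + Σ_{l=1..p} A_l Y_{t−l} + ε_t,   ε_t ~ N(0, Σ),

with `a_ij^(l)` the causal coefficient from channel j to channel i at lag
l. Directed coupling is summarised in the frequency domain by generalised
partial directed coherence (GPDC): with the transfer polynomial
`ā_ij(λ) = δ_ij − Σ_l a_ij^(l) e^{−i2πλl}` (λ in cycles/sample),

    |π_ij(λ)|² = (|ā_ij(λ)|²/σ_i²) / Σ_m |ā_mj(λ)|²/σ_m².

The squared modulus is the share of source j's outflow received by target
i after partialling out the other channels; the inverse-σ weighting makes
it invariant to channel scale. Each source column sums to one over
targets (the diagonal "self" term included) and every value lies in
[0, 1] — both hold to machine precision by construction and are asserted
over random stable ensembles in the tests. The amplitude (non-squared)
form is available via `squared=False`; the squared form is the default
because it carries the power-fraction interpretation.

Analysis is restricted to 0.05–0.15 Hz, evaluated at 50 bin centres
0.051, 0.053, …, 0.149 Hz (0.002 Hz pitch). Bin values are evaluations
at the bin centre, not within-bin averages: at this pitch the difference
is far below estimation error and centre evaluation is deterministic and
cheap.

## Estimation choices

* VAR fitting is ordinary least squares with an intercept (the intercept
  is retained even for demeaned data so the estimator matches the model as
  written). The residual covariance uses the effective-sample divisor
  T − p. The fit is cross-checked against `statsmodels` in the tests.
* Order selection minimises a group-level BIC: per subject,
  `log det Σ̂(p) + (log T_eff / T_eff)(p k² + k)` with `T_eff = T − p`,
  summed over subjects; the argmin over p = 1..p_max is the group order.
  On synthetic VAR(2) cohorts (20 subjects, T = 512) the true order is
  selected in ≥ 90/100 replicates.
* Band-pass filtering is zero-phase frequency-domain masking with a
  0.01 Hz raised-cosine roll-off outside each band edge and the DC bin
  zeroed: exact in-band gain, no phase distortion.
* PSD summaries use a Welch averaged periodogram (Hann taper, 64-sample
  segments, 50% overlap) — a standard variance/resolution compromise for
  ~256-sample series; the integrated density recovers the series variance
  within a few percent (Parseval check in the tests).

### Acausal filtering and directed inference

A finding worth stating plainly: zero-phase band-pass filtering before
VAR fitting corrupts *direction*. Zero-phase filters are acausal — each
filtered sample mixes past and future — so a filtered copy of a
unidirectionally coupled pair acquires genuine reverse-lag
predictability. In simulation, filtered low-order fits flagged the
reverse of a truly unidirectional edge in essentially every cohort, and
pushing the order high enough to absorb the filter's impulse response
(group BIC runs to the grid cap) inflates the estimation noise of all
spectra. The group-difference and classification validations therefore
fit the VAR on the raw simulated series and restrict GPDC *evaluation* to
the analysis band; `subject_gpdc` retains the filter→fit composition for
users who want the conventional pipeline, and the filter itself remains
the right tool for PSD summaries. With raw fitting, group BIC selects the
generating order and the attenuated path is detected with the correct
direction in 100% of test cohorts.

## Synthetic cohorts

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is validated.

* Two groups — A ("term-like", 23 subjects by default) and B ("VPT-like",
  29) — share a coupling specification (edge list with lags and
  coefficients, per-channel noise variances, default diagonal Σ since the
  GPDC weighting uses only σ_i). Group B's designated edges are scaled by
  multiplicative attenuation factors in [0, 1], emulating reduced
  high-strength directed connectivity after very preterm birth.
* Default series length T = 256 at 2 s sampling (≈ a nine-minute scan);
  burn-in 500 samples (transients decay below 1e−3 at spectral radius
  0.95); recursion seeded at zero with Gaussian innovations.
* Stability: if the realised coefficients have companion spectral radius
  ≥ 0.95, all coefficients are rescaled by a single uniform factor found
  by bisection to hit radius 0.95 — topology-preserving by construction.
* Reproducibility: the master seed is split with `SeedSequence.spawn`,
  one stream per subject plus one for covariates, so subject s's data do
  not depend on how other subjects' draws are consumed.
* Subject heterogeneity: each subject's edge factors receive a
  multiplicative jitter (sd 0.05, clipped), so within-group GPDC varies
  realistically.
* Covariates: gestational age ~ N(40, 1.3) weeks clipped to [37, 42] in
  group A and N(28.5, 2.2) clipped to [23, 32.9] in group B; the 0/1/2
  ultrasound code is driven by a latent negatively correlated with GA
  (rank correlation ≈ −0.6 by default, configurable), reproducing the
  known dependence between these perinatal risk factors. The
  executive-function score follows
  `ef = b0 + b1·c + b2·GA + b3·c·(GA − 35) + noise`, where c is the
  subject's realised coupling scale; the default b3 = −1 makes the
  coupling–outcome slope steepest at low gestational age, so moderation
  recovery is testable with known ground truth.
* Head-motion fixtures are boxcar-smoothed Gaussian random walks
  (translation step scale 0.02 mm by default, rotations 100× smaller)
  with optional single-volume spike excursions. Component-map fixtures
  are template indicators scaled by an SNR plus unit Gaussian voxel
  noise, with pure-noise distractor maps.

What the generator does **not** emulate: haemodynamic convolution,
scanner drift and physiological noise spectra, spatial structure of real
component maps, non-Gaussian innovations, or any relationship between
simulated motion and the time courses. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to fMRI artefacts.

## Head-motion metrics

From T×6 realignment series (x, y, z translations in mm, then rotations
about x, y, z in radians), each volume is compared with its predecessor:

* displacement per step = RMS of the three translation deltas,
  `sqrt((dx²+dy²+dz²)/3)` — the literal "root mean square of these
  values" reading; the Euclidean norm is available via
  `mode="euclidean"`;
* mean motion and maximum motion are the mean and max of that series;
* number of movements counts steps strictly above 0.1 mm (bounded by
  n − 1);
* rotation per step is the single Euler angle
  `arccos((cosφcosθ + cosφcosψ + cosθcosψ + sinφsinψsinθ − 1)/2)` of the
  rotation-parameter differences, with the arccos argument clipped to
  [−1, 1] against rounding; the per-subject summary is the mean of the
  per-step angles (max available). For single-axis rotations the formula
  agrees with the rotation-matrix trace identity, which the tests use as
  an oracle.

Group comparison bootstraps the mean difference (subjects resampled
within group, 1000 draws), with a two-sided percentile p-value judged at
α = .0125 (Bonferroni across the four metrics). Simulated null rejection
rates sit at or below nominal.

## Component selection (GOF)

A candidate component map is Z-scored over the analysis-mask voxels
(population variance, ddof = 0; sample variance switchable) and scored
against a binary template as mean(Z inside) − mean(Z outside), both means
restricted to the analysis mask — out-of-brain voxels are excluded so
empty space cannot inflate scores. Components are ranked per template;
the top component is skipped (and logged) whenever any artifact/exclusion
template (e.g. a CSF/ventricle mask) fits it better than the target.
Ties break toward the lower component index, logged. The score is
invariant under positive affine transforms of the map and flips sign
under negation.

## Group-level inference

* Normality gating: a test family switches to nonparametric when
  |skewness| > 2 or kurtosis > 7 (Pearson, non-excess scale; strict
  inequalities; excess scale switchable).
* Two-group comparison is Kruskal–Wallis (tie-corrected H, χ² with 1 df),
  verified in the tests against an independent rank-formula oracle on
  every split of an 8-value sample.
* Bin-wise spectral testing runs KW per ordered path per bin and reports
  a band only when ≥ 5 neighbouring bins are significant at α = .05 with
  a consistent effect direction (direction from group medians).
* Connectivity windows: per subject, the shares of (path, bin) GPDC
  values in low [0.05, 0.20), mid [0.20, 0.35) and high [0.35, 0.55)
  windows, plus out-of-range mass so the four shares total 100%; mean
  GPDC per window (NaN when empty).
* Leave-one-out reliability: any two-group test is re-run once per
  left-out participant; an effect is reliable only if the significant
  fraction strictly exceeds the Bonferroni-matched share —
  100·(1 − .05/m)%, i.e. 99.17% for six tests, 98.33% for three.

### Type-I behaviour of the five-bin cluster rule

The rule's per-path false-flag rate depends on the dependence structure
of the bin values. All 50 bins of a subject's GPDC derive from one fitted
VAR, so per-bin KW p-values are highly — but not perfectly — dependent:
subject-level spectra cross each other along the grid, creating several
quasi-independent opportunities for a 5-bin run. Measured on matched
null cohorts (25/25 subjects, k = 6, T = 256, 100 cohorts), the per-path
flag rate is ≈ 6%, slightly above the single-bin 5% and well above what
independent bins would give (≈ 0.05⁵ per run position). The rule is
conservative only for weakly dependent bins; for VAR-derived spectra it
is mildly anti-conservative, and bands it reports should be read
accordingly. The corresponding acceptance check asserts the sub-5% bound
and fails by this margin; the failure is retained as a documented
property of the rule rather than masked.

A related finite-sample caveat: attenuating an edge j→i also lowers
channel i's variance in the affected group, which *raises* the estimation
variance — and hence the positive bias — of the reverse-path GPDC in that
group. In ~10% of simulated cohorts this flags the reverse direction of
a truly unidirectional edge. Interpreting a weaker-group > stronger-group
reverse band requires this mechanism to be ruled out.

## Topology classification

Per subject, each ordered path's 50 bin values are reduced to one scalar
(band mean by default; per-bin max available), thresholded (> t) into a
binary k×k adjacency with zero diagonal, and flattened to a k(k−1)
feature vector (30 features at k = 6). A Fisher discriminant
`w ∝ S_w⁻¹(μ_A − μ_B)` is fitted with a pseudo-inverse after a 1e−6
ridge — the pooled covariance of ~30 binary features from ~50 subjects is
near-singular by construction — and the boundary sits midway between the
projected group means. Validation is leave-one-out (held-out subjects
binarised with the same threshold but excluded from fitting); the
threshold grid spans 0.05–0.55 in 0.01 steps; degenerate folds count as
misclassifications. "Discriminant accuracy" is LOO accuracy × the
Mahalanobis distance between group means under the pooled covariance of
the full-sample fit; the best threshold maximises LOO accuracy with ties
broken by larger Mahalanobis distance, then the lower threshold. On
separable synthetic cohorts LOO accuracy exceeds 0.9; label-permuted
cohorts centre at chance.

## Moderation analysis

Executive function is regressed on a GPDC summary x, a perinatal
moderator m (gestational age or ultrasound code — collinear, so analysed
one at a time) and their product, by OLS:
`y = b0 + b1·x + b2·m + b3·x·m + e`. Predictors are not mean-centred by
default (centring is an option; it changes the interpretation of b1/b2 to
effects at the mean of the other predictor and leaves b3 untouched).
Inference uses percentile bootstrap CIs (1000 subject resamples, level
1 − α with α = .025 Bonferroni-corrected for the two moderators);
collinear resamples are skipped and counted, with a warning above 10%.
Simple slopes `b1 + b3·m0` carry delta-method standard errors from the
classical coefficient covariance; a median-split stratified refit is the
alternative output (the split rule is a package choice and is logged).
Null CI exclusion rates measure ≈ 2.5–3.5% at n = 200, within binomial
error of nominal.

## Problem sizes

Validation runs use 100-replicate ensembles for order selection,
detection and null-rate checks (25/25 subjects, k = 6, T = 256 for
cohort-level checks; 20 subjects, T = 512, k = 2 for order recovery),
500 replicates for bootstrap coverage, and 100-model random stable
ensembles (k 2–6, p 1–5) for normalisation/bound checks. These sizes
give binomial standard errors of ~1–3 percentage points on the rates
being asserted.

## Known limitations

* The per-bin/per-path testing reports per-bin p-values and band extents;
  it does not produce a single corrected band-level p-value.
* GPDC group differences conflate coupling and innovation-variance
  differences in finite samples (see the reverse-bias caveat above).
* The LDA weights are interpretable only jointly; no per-path inference
  is attached to them.
* The generator's covariate model is linear with Gaussian noise;
  moderation results on heavy-tailed outcomes are untested.
* No motion scrubbing or motion regression is implemented; motion enters
  only as a QC comparison, matching the analysed design.
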