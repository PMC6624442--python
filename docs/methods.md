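# Methods

This note documents the generative model, the estimators, the numerical
choices, and the known limits of what the simulations can show.

## Observer model

Each simulated participant carries condition-wise true PSEs

    PSE(shadow, angle) = baseline + shadow·Δ_shadow
                         + Δ_orient(angle) + Δ_inter(shadow, angle)

and answers "comparison larger" with probability
`λ + (1 − 2λ)·Φ((x − PSE)/σ)` at comparison size `x`.  The cumulative
Gaussian with symmetric lapse mixing is the simplest standard
two-alternative forced-choice model; the symmetric mixing keeps
P = 0.5 exactly at the true PSE for any lapse rate, so lapses add
response noise without biasing the point the staircases converge on.
Only the standard stimulus can carry eyeshadow — comparison stimuli are
always eyeshadow-free, mirroring how such experiments construct their
comparison series — so only the standard's shadow flag enters the PSE.
Left/right stimulus position is logged as metadata and has no effect on
the response probability; no position-bias parameter is modelled.

Population structure: independent normal random effects on the baseline
PSE, the eyeshadow shift, and (optionally) orientation and interaction
shifts; slope and lapse rate are shared constants.  Defaults: 20
subjects, baseline 100% (SD 1%), eyeshadow shift +2.42% (SD 1%) for the
yaw design and +3.65% for the pitch design, zero orientation and
interaction effects, slope 2%, lapse rate 0.02.  The two mean shifts
are the empirically reported illusion magnitudes for the two rotation
axes; the variance components are not empirically constrained (subject-
level variances are generally not reported for this design), so the SDs
and slope are fixed at values that give effect sizes of the same order
as published studies, and are documented here as package defaults
rather than estimates.

## Staircase protocol

Comparison grid 92–108% in 1% steps.  Four staircases per block
(ascending from 92 / descending from 108 × eyeshadow on/off),
interleaved by a uniform random choice among non-terminated staircases
on every trial; one block per orientation, block order randomized per
subject.  1-up/1-down rule: "comparison larger" moves the next
comparison down one step, "standard larger" moves it up, so presented
levels concentrate around the 50% point of the psychometric function,
i.e. the true PSE.

Details the protocol description leaves open, fixed here as follows:

* **Reversal level** = the level *presented* on the trial whose response
  flipped the movement direction.  This keeps every recorded reversal an
  actually shown stimulus.
* **Boundaries** clamp at 92/108.  A clamped non-move still updates the
  movement direction but does not itself count as a reversal; reversals
  are defined purely by direction changes of the intended move.
* The first response of a staircase initializes its direction without a
  reversal.
* **Safety cap** `max_trials = 200` per staircase guarantees termination
  for pathological observers; capped staircases are flagged in the trial
  table and surfaced as warnings in the run manifest, never silently
  accepted.
* Deterministic test observers use a strict threshold rule ("comparison
  larger" iff level > threshold), which makes staircase trajectories
  exactly hand-checkable: an ascending staircase walks 92 → 101 and then
  oscillates, reversals alternating between 101 and 100.

## PSE estimation

The PSE of one subject × eyeshadow × orientation cell is the mean of the
reversal levels of the cell's two staircases.  Reversals are pooled
across the two staircases before averaging; a per-staircase-mean variant
is provided (`pooling="per_staircase"`), and the two agree exactly
whenever all staircases contribute equal reversal counts, which
termination at a fixed reversal criterion enforces.  All six reversals
are used; no early-reversal discard rule is applied.  Cells with no
reversals are a hard error: the downstream within-subject ANOVA needs a
complete balanced table, and silently dropping cells would corrupt it.

When analysing a stored trial log, reversal levels are recomputed by
replaying the logged responses through the staircase state machine in
trial order, so the estimate is invariant to row permutations and to
side metadata.

A known small-sample property, visible in the recovery studies: because
both staircases start eight steps from 100% but the true PSE of
eyeshadow standards sits above 100%, early reversals are slightly
asymmetric and the recovered illusion magnitude is biased a few
hundredths of a percent *downward* (about −0.15% at the default design,
i.e. within a sixth of one staircase step).  The bias shrinks with more
reversals and is well inside the quarter-step tolerance the test suite
enforces.

## Repeated-measures ANOVA

Classical univariate decomposition for a two-way fully within-subject
design: each effect is tested against its effect × subject interaction,
`F = MS_effect / MS_effect×subject`, with partial eta squared
`SS_effect / (SS_effect + SS_error) = F·df1/(F·df1 + df2)`.

Sphericity epsilons are computed from the orthonormal-contrast
covariance `S = CᵀΣ̂C` (Helmert contrasts; Kronecker products of the
factor contrasts for the interaction):

* Greenhouse–Geisser: `ε̂ = (tr S)² / (d · tr S²)`;
* Huynh–Feldt: `ε̃ = (n·d·ε̂ − 2) / (d·(n − 1 − d·ε̂))`, capped at 1;
* `cm`: the Lecoutre-corrected Huynh–Feldt estimator, which fixes the
  group-count term of the original multi-group formula.  For a
  single-group fully-within design the corrected numerator
  `(N − g + 1)` equals `N`, so `cm` and `hf` coincide exactly here;
  both are reported so the choice of estimator is always explicit.

The default reporting correction is `cm`; all three are stored in every
result.  Corrected p-values shrink both dfs by ε.  Two-level factors
have a single contrast and are exactly spherical (ε = 1).  Epsilons are
truncated to 1.00 at the reporting layer; CSV/JSON outputs keep full
precision.  Degenerate inputs (zero error variance) are flagged rather
than propagated as NaN: F is reported as 0 when the effect SS is also
zero and as infinity otherwise, with a `degenerate` flag either way.

## Bayes factors

Default-prior ANOVA model comparison.  For data vector y (one row per
subject × cell):

    y = μ1 + Σ_j X_j θ_j + ε,   ε ~ N(0, σ²I)
    p(μ, σ²) ∝ 1/σ²
    θ_j | g_j ~ N(0, g_j σ² I),   g_j ~ r_j² · Inv-χ²(1)

with one g per effect family (shadow, orientation, interaction,
subject), r = 1/2 for fixed families and r = 1 for subject.  Families
are sum-to-zero coded via orthonormal level contrasts; in the balanced
design the family blocks are mutually orthogonal with `X_jᵀX_j = c_j I`,
so conditional on g the marginal likelihood is closed-form:

    m(y|g) = Γ((N−1)/2) π^{−(N−1)/2} N^{−1/2}
             · Π_j (1 + g_j c_j)^{−p_j/2} · Q(g)^{−(N−1)/2}
    Q(g)   = ‖y − ȳ‖² − Σ_j [g_j c_j/(1 + g_j c_j)] ‖X_jᵀy‖²/c_j

obtained by integrating θ (normal), μ (flat) and σ² (Jeffreys)
analytically.  Because the priors act on standardized effects, every
Bayes factor is exactly invariant to rescaling the data.

Null-model conventions: each main effect is compared against the
intercept + subject model (the "no fixed effect" null, with the subject
family retained in both models); the interaction is compared against the
model with both main effects but no interaction.

The remaining 1–4-dimensional g integral is done in log-g space:

* **Importance sampling** (default for >2 dimensions): defensive mixture
  proposal, 30% prior / 70% multivariate normal at the joint mode of
  prior × conditional marginal (Nelder–Mead mode search,
  finite-difference Hessian, covariance inflated 2×).  10⁵ samples by
  default; the relative Monte-Carlo standard error is estimated from the
  weight variance and results above 5% relative error are flagged as
  non-converged, never silently accepted.
* **Quadrature** (default for ≤2 dimensions): a wide fixed-step grid
  centred on the same mode (±12 posterior SDs plus margin, 401 points
  per dimension); deterministic, error reported as 0.

Both routes are validated against brute-force oracles in the test
suite: the closed-form conditional marginal against tensor-product
Gauss–Hermite/trapezoid integration over all model parameters, and the
g integral against a dense fixed grid in log-g.  Comparing a model with
itself short-circuits to BF = 1 (the two marginals are the same
integral).  Interpretation bands: BF < 1/10 strong and 1/10–1/3
substantial evidence for the null; 3–10 substantial and > 10 strong
evidence for the alternative; 1/3–3 inconclusive.

## Pipeline and reproducibility

A single global seed is expanded through `numpy.random.SeedSequence`
into per-stage and per-subject child streams (population sampling, each
subject's staircases, each Bayes-factor integration), so any stage can
be rerun in isolation and full runs are byte-reproducible; the run
manifest records the config hash, seed, package versions and all
warnings.  Percent-of-original-eye-size is the unit everywhere; no
pixel or visual-angle conversions are performed.  Replicate studies
(type-I calibration, parameter recovery) use a record-free staircase
runner that skips trial-log allocation; its equivalence to the logged
path is itself a test.

Problem sizes: the calibration study uses 1,000 full-protocol replicates
of the 20-subject design and the recovery study 200; the brute-force
Bayes oracles run on a 4-subject × 2-condition toy table, where
12-node-per-dimension Gauss–Hermite quadrature is accurate to better
than three significant digits on the log marginal.

## What the simulations do and do not show

The generator reproduces the design's structure (balanced within-subject
factorial, adaptive staircases, binary judgments) and its reported
effect sizes, but real observers differ in ways the model omits:
sequential dependencies (learning, fatigue, response perseveration),
asymmetric or non-Gaussian psychometric functions, position biases,
stimulus-level idiosyncrasies of rendered faces, and any true
orientation dependence of the illusion.  Passing calibration and
recovery tests therefore certifies the *analysis chain* under the
assumed observer model — not the psychological conclusions drawn from
any particular human dataset.  Published headline statistics from human
data (specific F or BF values) are not reproduction targets: they
depend on unreleased raw data, and only their analytic identities
(e.g. F, df → η_p²) are recomputable exactly.
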