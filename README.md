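# illusim

Simulation and analysis of staircase-measured face illusions — in
particular the *eyeshadow illusion*, the overestimation of eye size
induced by eyeshadow on the upper eyelids, and the question of whether
its magnitude depends on face orientation (yaw or pitch rotation).

The package is written for visual psychophysicists and methodologists who
want to study this measurement chain *in silico*: power analysis, type-I
calibration, estimator bias, and the behaviour of the Bayesian
model-comparison step, all under a fully specified generative model of
the experiment.

## What it implements

**Observer model.** A simulated participant judges, on each trial,
whether a comparison face's eyes look larger than a standard face's
eyes.  The probability of answering "comparison larger" is a lapse-mixed
cumulative Gaussian of the comparison eye size *x* (percent of the
original eye size):

    P(comparison larger) = λ + (1 − 2λ) Φ((x − PSE) / σ)

where the condition-wise point of subjective equality is
`PSE = baseline + shadow·Δ_shadow + Δ_orientation(angle) + Δ_interaction(shadow, angle)`,
with independent normal between-subject random effects on every
component.  Setting all interaction terms to zero generates a
viewpoint-invariant illusion.

**Staircase protocol.**  Each block measures one face orientation and
runs four randomly interleaved 1-up/1-down staircases (ascending from
92% / descending from 108%, crossed with eyeshadow on/off on the
standard) on a 92–108% grid in 1% steps.  A staircase terminates after
six direction reversals; the PSE estimate of a design cell is the mean
of its staircases' reversal levels.

**Inference.**  The subject × eyeshadow × orientation PSE table feeds

* a two-way fully within-subject ANOVA (each effect tested against its
  effect-by-subject mean square), with partial eta squared
  `η_p² = F·df1 / (F·df1 + df2)` and sphericity corrections
  (Greenhouse–Geisser, Huynh–Feldt, and the Lecoutre-corrected
  Huynh–Feldt ε, applied to both degrees of freedom), and
* default g-prior Bayes factors for the three targeted comparisons: each
  main effect against the intercept-plus-subject null, and the
  interaction against the two-main-effects model.  Effects are
  sum-to-zero coded with one g per family; g carries a scaled
  inverse-χ²(1, r²) prior with r = 1/2 (fixed) and r = 1 (subject).
  Conditional on g the marginal likelihood is closed-form; the g integral
  uses seeded importance sampling (defensive Laplace/prior mixture) or
  deterministic quadrature for small models.

## Worked example

```bash
illusim run --config exp1 --out results/exp1 --verbose
```

runs the bundled yaw-rotation design — 20 subjects, orientations 0°,
±30°, ±60°, a true mean eyeshadow shift of +2.42% with SD 1%, slope 2%,
2% lapses — and prints the report the pipeline wrote:

```
Simulated experiment 'exp1' (yaw rotation, angles [-60.0, -30.0, 0.0, 30.0, 60.0])
seed = 1, n_subjects = 20

Eyeshadow illusion magnitude (PSE shadow - PSE no-shadow):
  grand mean = 1.94% (SD 1.00, SE 0.22)
  angle -60: 1.57% (SE 0.29)
  angle -30: 1.97% (SE 0.34)
  angle +0: 1.98% (SE 0.36)
  angle +30: 1.90% (SE 0.30)
  angle +60: 2.29% (SE 0.38)

Two-way repeated measures ANOVA (n = 20, epsilon: cm)
  shadow: F(1, 19) = 75.80, etap2 = .800, p < .001, eps = 1.00
  orientation: F(3.84, 73.05) = 0.34, etap2 = .018, p = .843, eps = 0.96
  interaction: F(4, 76) = 0.84, etap2 = .042, p = .506, eps = 1.00

Bayes factors:
  shadow: BF = 1.08 x 10^29 (strong-alternative)
  orientation: BF = 0.02 (strong-null)
  interaction: BF = 0.10 (substantial-null)
```

Reading: the simulated observers' eyeshadow illusion is recovered
(grand mean 1.94% against this population draw's realized truth near
2.4%), the shadow main effect is decisive, and — because the generating
model is viewpoint-invariant — the interaction Bayes factor lands in a
null-evidence band (BF < 1/3), the package's analogue of the evidence
pattern such an experiment is designed to probe.  All outputs
(`trials.csv`, `pse.csv`, `anova.csv`, `bayes_factors.json`,
`manifest.json`, `report.txt`) are byte-reproducible from the config and
seed.

The same machinery is available as a library (`illusim.run_pipeline`,
`illusim.simulate_replicate`, `illusim.two_way_rm_anova`,
`illusim.bayes_factor`, ...), and `illusim recover` runs replicate
parameter-recovery studies.

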