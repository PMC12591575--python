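# Methods

This note documents the generative models, estimators, default parameters, and
numerical choices implemented in `vexpect`. Everything quantitative stated here
is computed by the package itself (see `analysis/` and the test suite); no
empirical claim about human participants is made.

## Scientific setting

The package models a violation-of-expectations (VE) paradigm comparing a
neurotypical group (NT) with a cerebellar-ataxia group (CA) across three tasks:

1. **Experiment 1 — arithmetic verification.** Participants verify chained
   subtraction equations (e.g. `9 - 5 - 1 = 3`). Half of the displayed
   solutions are correct ("expected"), half deviate from the correct result by
   ±1 ("unexpected"); complexity is one vs. two subtrahends.
2. **Experiment 2 — letter-transformation verification.** A rule of the form
   "+k" shifts each source letter k steps along the alphabet (`C M | +1 | D N`).
   Shown solutions are the true transformation (expected) or a one-letter ±1
   deviation (unexpected); complexity is the number of letters (1–4 reduced to
   a low/high contrast in analysis).
3. **Experiment 3 — artificial grammar learning (AGL).** After exposure to
   strings from a finite-state grammar, participants judge the grammaticality
   of novel test strings crossing grammaticality with chunk-strength similarity
   (high/low). Performance is scored with equal-variance signal detection.

The scientific question the effect structure encodes: VE effects (slower
responses to unexpected outcomes) are present in both groups but *larger* in
the CA group, and implicit sensitivity to sequential structure (the
low-similarity d′ advantage) is reduced in the CA group.

## Stimulus generators

### Grammar (`vexpect.grammar`)

The grammar is a finite-state machine: states, lettered transitions, entry
(state, letter) pairs, and exit states. Acceptance is evaluated by
nondeterministic state-set simulation (linear in string length); the test
suite cross-checks it against an exhaustive depth-first path enumeration on
every string up to length 6. The bundled default grammar
(`data/grammar_default.yaml`) is a five-state machine over {X, V, J, T}
generating 52 distinct strings of length 2–6.

**Chunk strength** of a test string is the mean training frequency of its
contiguous bigrams and trigrams: with L letters the denominator is
(L−1) + max(L−2, 0). Tables can be unique-string or presentation-weighted.
The 2×2 test set (grammatical × similarity) is built by a median split on
chunk strength within each grammaticality class, using a stable sort on
(similarity, string) so ties resolve deterministically and cells are exactly
balanced (8 strings per cell, each shown 3 times → 96 test trials; training
is 23 strings × 4 repetitions = 92 trials).

### Verification tasks (`vexpect.stimuli`)

Both RT-task generators enforce: unique left-hand sides across the set, all
partial results within the digit range 0–9 (Experiment 1) or the alphabet
(Experiment 2), exactly balanced expectancy × complexity cells, and ±1 lure
signs balanced via a needs-based assignment (boundary items whose correct
answer admits only one lure direction are forced; flexible items absorb the
remaining need). Sessions add randomized trial order, three attention probes,
and a midpoint break.

## Data-generating models (`vexpect.simulate`)

### Response times (Experiments 1–2)

Latent mean RT for participant *i* in cell (expectancy e, complexity x):

```
mu_i(e, x) = baseline + group_offset·[CA] + expectancy_g·[unexpected]
           + complexity_g·[high] + b_i,     b_i ~ N(0, intercept_sd²)
```

with per-group effect sizes `expectancy_g`, `complexity_g`. Residuals are
lognormal by default, with the lognormal parameters solved so each cell's
mean and SD on the millisecond scale equal `mu` and `residual_sd` exactly;
a plain-normal family is available and is used by the recovery harness, where
additive cell-mean truths must be exactly identified. RTs at or beyond the
deadline are censored to non-responses (empty response, `correct = False`).
Accuracy is Bernoulli per group, independent of RT.

Default parameters (units ms):

| parameter | Exp 1 | Exp 2 | rationale |
|---|---|---|---|
| n per group | 15 | 26 | study group sizes |
| baseline | 2000 | 3400 | sets grand means near ≈2.7 s / ≈5.0 s so the deadline (5 s / 10 s) censors ≲0.1% of trials and censoring bias stays far below the Monte-Carlo SE |
| group offset | 304 | 1470 | injected group main effect |
| expectancy NT/CA | 238 / 398 | 327 / 699 | NT simple effect and NT+interaction |
| complexity NT/CA | 831 / 910 | 1129 / 1237 | likewise |
| intercept SD / residual SD | 350 / 300 | 500 / 500 | plausible between/within spread; large enough that the mixed model's variance components are well identified |

### Grammaticality judgments (Experiment 3)

Equal-variance signal detection per group × similarity cell:
`P("grammatical") = Φ(d′/2 − c)` for grammatical strings and `Φ(−d′/2 − c)`
for nongrammatical strings. Default truths: d′ NT high/low = 0.173/0.808,
CA high/low = 0.169/0.344 (so the NT low−high contrast is 0.635, the NT−CA
low-similarity contrast 0.464, and the implied interaction 0.460); criterion
c = 0 for NT and 0.348/0.234 for CA high/low. The NT-high anchor was chosen
so simulated grand accuracy lands near 57%, i.e. modestly above chance, as
expected for implicit learning. Judgment RTs (lognormal, mean 2568/2815 ms
by group) are generated for completeness but are not analysis targets.

### Exclusions

Whole participants are removed for (a) overall accuracy below 50% and (b) any
failed attention probe. Both rules apply in Experiments 1–2; Experiment 3
applies only the probe rule, because with true accuracy near 57% a
below-chance cut would truncate the sampling distribution and bias group-level
d′ upward.

## Estimators

### SDT scoring (`vexpect.sdt`)

d′ = z(H) − z(F); c = −(z(H) + z(F))/2, computed per participant ×
similarity (24 grammatical and 24 nongrammatical trials per cell).
**Extreme-proportion handling:** the default is the log-linear correction
(k + 0.5)/(N + 1) applied to every cell. The alternative "replace" rule
(0 → 1/(2N), 1 → 1 − 1/(2N), other cells untouched) is available but not the
default: exact enumeration over the binomial response distribution at the
default truths shows the replacement rule biases the recovered NT low−high
contrast by about +0.025 and the NT−CA low contrast by about +0.018 (≈3 and
≈2 Monte-Carlo SEs at 200 replicates), whereas log-linear leaves residual
biases of about −0.006 and −0.004. The correction is a parameter of every
scoring entry point and is recorded in outputs.

### Mixed models (`vexpect.inference`)

`fit_lme` fits a linear mixed model with the full factorial fixed-effect
design and participant random intercepts by REML, delegating to statsmodels
`MixedLM`. Factors are effect-coded at ±1/2 (second level positive:
CA, unexpected, high complexity, low similarity), so a main-effect coefficient
is the marginal level difference and simple effects are linear contrasts,
e.g. the NT expectancy simple effect is β_expectancy − ½·β_group:expectancy.
p-values use the large-sample Wald-normal approximation; the method is
recorded in the result metadata, and a `singular` flag marks fits whose
random-intercept variance collapsed.

Two numerical choices deserve note:

- **Fixed-effect covariance.** For a random-intercept model,
  V_i = σ²I + τ²11′, so X′V⁻¹X accumulates in closed form per participant.
  The covariance is computed analytically at the REML variance estimates
  rather than from the numerical Hessian, which is occasionally indefinite on
  these designs.
- **Optimizer.** The fit uses the default BFGS first and accepts a solution
  only if it converged with finite log-likelihood, falling back to Powell.
  This guards against a failure mode observed with L-BFGS where a boundary
  solution reported infinite log-likelihood, zero random-effect variance, and
  minimum-norm (zero) estimates for between-subject terms.

### Power (`power_n_per_group`)

Smallest per-group n for a two-sample test, iterating the exact noncentral-t
power expression (normal approximation available). d = 1.36, α = .05,
power = .95 gives n = 13 one-tailed and 16 two-tailed; d = 1.0 at power .80
two-tailed gives 17.

## Monte-Carlo parameter recovery (`vexpect.recovery`)

Each replicate regenerates the stimulus set, simulates a full dataset from
known truths (normal RT family), applies the exclusion rules, and re-estimates
via the same scoring/fitting pipeline used for analysis. Child seeds come
from `numpy.random.SeedSequence(seed).spawn(R)`, so replicates are independent
and the whole study is reproducible from one integer. Reports give the truth,
Monte-Carlo mean, bias, MC SE (= SD/√R), and rejection rate at α = .05 per
tracked contrast; failed replicates are dropped and counted. A companion
all-null generator calibrates the type-I error of the group × expectancy test.

## Generator realism: what is and is not modeled

The generator reproduces the *statistical structure the analyses assume* — not
behavior. Known simplifications: accuracy is independent of RT and of
expectancy/complexity (no speed–accuracy trade-off, no error-related slowing);
RT residuals are i.i.d. within participant (no sequential effects, fatigue, or
learning across trials); the SDT model has no trial-level similarity gradient,
only the binary high/low contrast; lapses are off by default; attention-probe
failures are independent Bernoulli events. Consequently the package can
validate estimator correctness and calibration, but cannot adjudicate between
psychological accounts of the effects.

## Limitations

- Acceptance of the pipeline rests on parameter recovery of injected truths;
  agreement with any particular empirical dataset is out of scope.
- The bundled grammar is a synthetic transcription constrained to satisfy the
  documented string examples, not a copy of any published stimulus list, so
  chunk-strength summary values of specific historical string sets are not
  reproducible here.
- Mixed-model p-values use the normal approximation; at these sample sizes a
  Satterthwaite or Kenward-Roger correction would be slightly more
  conservative.
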