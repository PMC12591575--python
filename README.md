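# vexpect

Synthesis and analysis of violation-of-expectations (VE) experiments
comparing a neurotypical (NT) group with a cerebellar-ataxia (CA) group.

The package implements the full experimental stack for three tasks —
arithmetic verification, letter-transformation verification, and artificial
grammar learning (AGL) — as a *simulation-and-recovery* framework: stimulus
generators with the exact design constraints, a trial-level behavioral data
generator with known ground-truth effects, the scoring and mixed-model
estimators used to analyze such data, and a Monte-Carlo harness that verifies
the estimators recover the injected truths without bias.

## Science in brief

The VE paradigm measures how strongly an incorrect ("unexpected") outcome
slows verification relative to a correct ("expected") one. The effect
structure built into the default generators encodes the hypothesis pattern of
interest: VE slowing is present in both groups but larger in the CA group
(a group × expectancy interaction), problem complexity slows everyone,
and in the AGL task implicit sensitivity to sequential structure — the d′
advantage for low-similarity strings, where chunk familiarity cannot carry the
judgment — is reduced in the CA group.

Models and estimators:

- **Stimuli.** Chained subtractions with all partial results in 0–9, unique
  equations, balanced ±1 lures (64 trials, 2×2 expectancy × complexity);
  letter-transformation problems under alphabet-successor rules (96 problems);
  a five-state finite-state grammar with chunk-strength-based 2×2 test-set
  categorization (92 training trials, 32 novel test strings × 3).
- **Generator.** RT = baseline + group offset + per-group expectancy and
  complexity effects + participant random intercept + lognormal (or normal)
  residual, censored at the task deadline; AGL judgments from equal-variance
  signal detection with per group × similarity d′ and criterion.
- **Estimators.** Per-participant effect scores; log-linear-corrected d′/c;
  REML linear mixed models (participant random intercepts, effect-coded ±1/2
  factors, simple effects as linear contrasts) via statsmodels; exact
  noncentral-t power iteration.
- **Validation.** Seeded Monte-Carlo parameter recovery (bias, MC SE,
  rejection rates) plus type-I calibration under an all-null generator.

See `docs/methods.md` for model equations, default parameters with rationale,
numerical choices, and limitations.

## Worked example

Run the full seeded pipeline (stimuli → simulate → exclude → score → fit →
report) for the arithmetic-verification experiment:

```bash
vexpect run --experiment 1 --seed 2026 --out results/runs/exp1
cat results/runs/exp1/report.txt
```

Output (abridged; your numbers will match exactly for the same seed):

```
vexpect run (experiment 1, seed 2026)

session_trials: 64
trials: 2010
excluded_participants: 0

estimates:
                expectancy  est=   314.815  se=  14.903  p=4.803e-99
                complexity  est=   847.216  se=  14.900  p=0
          group:expectancy  est=   114.908  se=  29.807  p=0.0001157
             expectancy|NT  est=   257.361  se=  20.829  p=4.526e-35
             expectancy|CA  est=   372.269  se=  21.321  p=2.882e-68
```

With 15 participants per group, a single simulated dataset scatters around the
generating truths (NT expectancy 238 ms, interaction 160 ms); averaging over
replicates recovers them. The same in Python, for the AGL experiment:

```python
from vexpect import default_config, simulate_dataset, score_sdt, fit_lme

records, exclusions = simulate_dataset(default_config(3), rng=2026)
table = fit_lme(score_sdt(records), ["group", "similarity"], outcome="dprime")
print(table[table.term == "similarity|NT"])
#             term  estimate        se         p  singular
# 4  similarity|NT    0.5339  0.120268  0.000009      True
```

(The `singular` flag marks draws where the participant-intercept variance
collapsed to zero — common with only two d′ values per participant and
harmless for the fixed-effect contrasts.)

Monte-Carlo recovery of the generating effects (200 replicates):

```bash
vexpect recover --experiment 1 --reps 200 --seed 2026 --out results/recovery_exp1.csv
```

```
       parameter  true  mean_estimate      bias    mc_se  rejection_rate
   expectancy|NT 238.0     236.584080 -1.415920 1.486040           1.000
   complexity|NT 831.0     831.786877  0.786877 1.408690           1.000
group:expectancy 160.0     160.875032  0.875032 2.230108           1.000
group:complexity  79.0      77.572522 -1.427478 2.048486           0.765
```

Every bias is within two Monte-Carlo standard errors of zero.

## Command-line interface

`vexpect` exposes `generate-stimuli`, `simulate`, `analyze`, `recover`,
`report`, and `run` subcommands; all take `--seed`/`--out` and accept a YAML
generator configuration via `--config` (bundled defaults:
`src/vexpect/data/experiment{1,2,3}.yaml`) and a grammar file via `--grammar`.

## Layout

```
src/vexpect/       library (grammar, stimuli, config, simulate, sdt,
                   inference, recovery, io, pipeline, cli)
src/vexpect/data/  default grammar + per-experiment generator configs (YAML)
analysis/          numbered reproduction drivers (write to results/)
scripts/           acceptance.py (recompute headline quantities)
tests/             unit, property-based, and acceptance tests
docs/methods.md    model and estimator documentation
```
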