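# Artificial-grammar-judgment generator defaults.
# d' cell truths encode the group-level contrasts: NT low-high = 0.635,
# NT-CA difference in low similarity = 0.464, in high similarity = 0.004
# (implied group-by-similarity interaction 0.460).  The NT high anchor
# (0.173) sets grand accuracy to ~57.4%.  Criterion: NT unbiased; CA mean
# bias 0.291 with a 0.114 similarity modulation.  No response deadline and
# group-equal RT variability; only the attention-probe exclusion rule
# applies in this task (near-chance accuracy is expected, not an artifact).
experiment: 3
n_per_group: 20
groups: [NT, CA]
baseline_ms: 2568.0
group_offset_ms: 247.0
expectancy_ms: {NT: 0.0, CA: 0.0}
complexity_ms: {NT: 0.0, CA: 0.0}
intercept_sd_ms: 400.0
residual_sd_ms: 700.0
family: lognormal
deadline_ms: null
accuracy: {NT: 0.574, CA: 0.574}
dprime:
  NT: {high: 0.173, low: 0.808}
  CA: {high: 0.169, low: 0.344}
criterion:
  NT: {high: 0.0, low: 0.0}
  CA: {high: 0.348, low: 0.234}
agl_rt_mean_ms: {NT: 2568.0, CA: 2815.0}
agl_rt_sd_ms: 700.0
lapse_rate: 0.0
probe_fail_prob: 0.0
exclusion_rules: [probe-failure]
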