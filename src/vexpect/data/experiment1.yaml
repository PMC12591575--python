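# Subtraction-verification generator defaults.
# Fixed effects (ms) are the group-level estimates the recovery harness
# injects as truths: NT expectancy 238 with a +160 group-by-expectancy
# interaction, NT complexity 831 with +79, group offset 304.  Baseline and
# variance components are chosen so the grand mean is ~2.7 s (the task runs
# around the 3 s range) and the 5 s response deadline is rarely binding.
experiment: 1
n_per_group: 15
groups: [NT, CA]
baseline_ms: 2000.0
group_offset_ms: 304.0
expectancy_ms: {NT: 238.0, CA: 398.0}
complexity_ms: {NT: 831.0, CA: 910.0}
intercept_sd_ms: 350.0
residual_sd_ms: 300.0
family: lognormal
deadline_ms: 5000.0
accuracy: {NT: 0.91, CA: 0.88}
lapse_rate: 0.0
probe_fail_prob: 0.0
exclusion_rules: [below-chance, probe-failure]
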