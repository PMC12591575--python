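# Alphabet-transformation generator defaults.
# NT expectancy 327 with +372 group-by-expectancy interaction, NT complexity
# 1129 with +108, group offset 1470; grand mean ~5.0 s, 10 s deadline.
experiment: 2
n_per_group: 26
groups: [NT, CA]
baseline_ms: 3400.0
group_offset_ms: 1470.0
expectancy_ms: {NT: 327.0, CA: 699.0}
complexity_ms: {NT: 1129.0, CA: 1237.0}
intercept_sd_ms: 500.0
residual_sd_ms: 500.0
family: lognormal
deadline_ms: 10000.0
accuracy: {NT: 0.75, CA: 0.76}
lapse_rate: 0.0
probe_fail_prob: 0.0
exclusion_rules: [below-chance, probe-failure]
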