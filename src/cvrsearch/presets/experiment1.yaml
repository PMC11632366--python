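# Preclinical secondary-prevention trial: cognitively unimpaired cohort,
# two visits separated by 54 months, 80% power to detect a 20% slope reduction.
group: CU
visit_times: [0.0, 4.5]
power: 0.80
alpha: 0.05
pct_change: 0.20
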