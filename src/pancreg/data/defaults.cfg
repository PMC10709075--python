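# Baseline inputs: projected 2021 statewide cohort, fractions in [0,1], costs in USD.
annual_incidence: 5958
p_resectable: 0.41
p_resection: 0.40
p_hvc: 0.466
hvc_mortality_30d: 0.018
hvc_complication_30d: 0.343
lvc_mortality_30d: 0.052
lvc_complication_30d: 0.398
cost_per_complication_hvc: 16815
cost_per_complication_lvc: 16815
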