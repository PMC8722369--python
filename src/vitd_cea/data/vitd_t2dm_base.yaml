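# Base-case inputs for the vitamin D / T2DM decision-tree model.
# One-year horizon; costs in 2018 USD per person; utilities are
# one-year QALY weights. Any key omitted here falls back to the same
# bundled default, so this file doubles as the schema reference.

# Vitamin D status probabilities without supplementation
p_def_pre: 0.76
p_suf_pre: 0.24
# ... and after the nine-month supplementation course.
# Sufficiency is the normalized complement of deficiency.
p_def_post: 0.172
p_suf_post: 0.828
# Diabetes risk conditional on vitamin D status
p_dm_def: 0.128
p_dm_suf: 0.07
# Costs (USD/person/year)
c_vitd: 0.61
c_dm: 710
# Health-state utilities (QALY weights)
u_dm: 0.59
u_healthy: 0.76
# Willingness-to-pay band (USD/QALY)
wtp_low: 1032
wtp_high: 2666
# Sampling distributions for probabilistic sensitivity analysis.
# family: gamma | beta | fixed; mean/sd on the parameter's own scale.
psa:
  c_vitd: {family: gamma, mean: 0.61, sd: 0.12}
  c_dm: {family: gamma, mean: 710, sd: 70}
  u_dm: {family: beta, mean: 0.59, sd: 0.15}
  u_healthy: {family: fixed, mean: 0.76}
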