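# Two-strategy decision model: universal vitamin D supplementation of
# Iranian high-school students versus no intervention, one-year horizon.
#
# Structure: each student is vitamin D deficient or sufficient (the
# deficiency probability depends on the arm), then develops depression or
# not (the depression probability depends on vitamin D status).  Depressed
# students incur the one-year depression-management cost and the depressed
# utility weight; everyone in the supplementation arm additionally incurs
# the per-student programme cost, modelled as a strategy-level upfront cost.
#
# Post-supplementation vitamin D status uses deficiency 0.172 with the
# sufficiency branch as its complement (0.828): the two published
# percentages (17.2% and 87.2%) do not sum to one, and the complement form
# is the normalization that reproduces the published base-case results.
#
# Costs are 2018 USD; utilities are one-year QALY weights.  Uncertain
# parameters carry mean +/- SD with the distribution family used in
# probabilistic sensitivity analysis; probabilities are fixed.

name: vitd_iran_2018
intervention: vitamin_d_supplementation
comparator: no_intervention
wtp_thresholds: [1032, 2666]

parameters:
  p_deficient_untreated:
    role: probability
    value: 0.76
  p_deficient_supplemented:
    role: probability
    value: 0.172
  p_depression_deficient:
    role: probability
    value: 0.314
  p_depression_sufficient:
    role: probability
    value: 0.16
  u_healthy:
    role: utility
    family: beta
    mean: 0.760
    sd: 0.070
    units: QALY
  u_depressed:
    role: utility
    family: beta
    mean: 0.545
    sd: 0.035
    units: QALY
  c_depression_management:
    role: cost
    family: gamma
    mean: 335.4
    sd: 35
    units: USD
  c_supplementation:
    role: cost
    family: gamma
    mean: 0.604
    sd: 0.120
    units: USD

strategies:
  - name: no_intervention
    upfront_cost: 0
    root:
      label: vitamin_d_status
      branches:
        - label: deficient
          p: p_deficient_untreated
          node:
            label: depression_status
            branches:
              - label: depressed
                p: p_depression_deficient
                node:
                  cost: c_depression_management
                  utility: u_depressed
                  tags: [depressed]
              - label: healthy
                p: complement
                node:
                  cost: 0
                  utility: u_healthy
        - label: sufficient
          p: complement
          node:
            label: depression_status
            branches:
              - label: depressed
                p: p_depression_sufficient
                node:
                  cost: c_depression_management
                  utility: u_depressed
                  tags: [depressed]
              - label: healthy
                p: complement
                node:
                  cost: 0
                  utility: u_healthy

  - name: vitamin_d_supplementation
    upfront_cost: c_supplementation
    root:
      label: vitamin_d_status
      branches:
        - label: deficient
          p: p_deficient_supplemented
          node:
            label: depression_status
            branches:
              - label: depressed
                p: p_depression_deficient
                node:
                  cost: c_depression_management
                  utility: u_depressed
                  tags: [depressed]
              - label: healthy
                p: complement
                node:
                  cost: 0
                  utility: u_healthy
        - label: sufficient
          p: complement
          node:
            label: depression_status
            branches:
              - label: depressed
                p: p_depression_sufficient
                node:
                  cost: c_depression_management
                  utility: u_depressed
                  tags: [depressed]
              - label: healthy
                p: complement
                node:
                  cost: 0
                  utility: u_healthy
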