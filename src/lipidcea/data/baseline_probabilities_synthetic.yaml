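# SYNTHETIC baseline transition probabilities for the statin comparator arm.
#
# Annual probabilities of each event type, by health state, for the statin
# monotherapy arm of each drug's source trial population.  These are
# synthetic stand-ins: their magnitudes emulate the published control-arm
# event rates of large cardiovascular outcome trials in statin-treated
# populations (annualized over median follow-up, and split between patients
# with and without established CVD using the baseline CVD prevalence and a
# CVD-vs-non-CVD relative risk of 2), but they are NOT transcriptions of any
# published table.  Replace this file with transcribed values to reproduce a
# specific published analysis.
provenance: synthetic
drugs:
  icosapent_ethyl:              # REDUCE-IT-like population, ~71% with CVD
    alive_without_cvd:
      nonfatal_mi: 0.0108
      nonfatal_stroke: 0.0040
      unstable_angina_hosp: 0.0047
      coronary_revasc: 0.0168
      cvd_death: 0.0063
      noncvd_death: 0.0045
    alive_with_cvd:
      nonfatal_mi: 0.0216
      nonfatal_stroke: 0.0080
      unstable_angina_hosp: 0.0094
      coronary_revasc: 0.0336
      cvd_death: 0.0126
      noncvd_death: 0.0060
  evolocumab:                   # FOURIER-like population, all with CVD
    alive_without_cvd:          # unused in the supported secondary setting
      nonfatal_mi: 0.0107
      nonfatal_stroke: 0.0044
      unstable_angina_hosp: 0.0040
      coronary_revasc: 0.0163
      cvd_death: 0.0040
      noncvd_death: 0.0045
    alive_with_cvd:
      nonfatal_mi: 0.0213
      nonfatal_stroke: 0.0087
      unstable_angina_hosp: 0.0079
      coronary_revasc: 0.0325
      cvd_death: 0.0079
      noncvd_death: 0.0064
  alirocumab:                   # ODYSSEY-like post-ACS population
    alive_without_cvd:
      nonfatal_mi: 0.0141
      nonfatal_stroke: 0.0029
      unstable_angina_hosp: 0.0011
      coronary_revasc: 0.0162
      cvd_death: 0.0045
      noncvd_death: 0.0043
    alive_with_cvd:
      nonfatal_mi: 0.0282
      nonfatal_stroke: 0.0058
      unstable_angina_hosp: 0.0022
      coronary_revasc: 0.0323
      cvd_death: 0.0090
      noncvd_death: 0.0086
  ezetimibe:                    # IMPROVE-IT-like post-ACS population
    alive_without_cvd:
      nonfatal_mi: 0.0132
      nonfatal_stroke: 0.0040
      unstable_angina_hosp: 0.0018
      coronary_revasc: 0.0217
      cvd_death: 0.0059
      noncvd_death: 0.0055
    alive_with_cvd:
      nonfatal_mi: 0.0263
      nonfatal_stroke: 0.0080
      unstable_angina_hosp: 0.0035
      coronary_revasc: 0.0434
      cvd_death: 0.0117
      noncvd_death: 0.0110
  fibrate:                      # ACCORD-like diabetic population, ~37% with CVD
    alive_without_cvd:
      nonfatal_mi: 0.0103
      nonfatal_stroke: 0.0033
      unstable_angina_hosp: 0.0088
      coronary_revasc: 0.0147
      cvd_death: 0.0045
      noncvd_death: 0.0075
    alive_with_cvd:
      nonfatal_mi: 0.0205
      nonfatal_stroke: 0.0066
      unstable_angina_hosp: 0.0176
      coronary_revasc: 0.0293
      cvd_death: 0.0091
      noncvd_death: 0.0150
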