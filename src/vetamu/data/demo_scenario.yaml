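# Packaged demo scenario: a moderate multi-practice cohort (2018-2022)
# with the default clinical rates; used in docs and the test suite.
n_practices: 12
patients_per_practice: [150, 400]
species_mix: 0.58
years: [2018, 2022]
consult_rate: 1.1
p_treat:
  dog: 0.129
  cat: 0.225
p_multi_substance: 0.115
p_followup:
  dog: 0.231
  cat: 0.387
p_change: 0.13
p_indication_text: 0.433
p_human_product: 0.044
p_return_untreated: 0.18
practice_dispersion: 0.35
p_death: 0.02
p_crossbreed: 0.24
p_missing_breed: 0.17
seed: 42
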