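# Machine-readable item dictionary for assessment CSV files.
#
# Self-performance ADL items use the home-care coding
#   0 independent .. 6 total dependence, 8 "activity did not occur";
# code 8 is treated as maximal dependence throughout (configurable recode).
# IADL items use the 0-2 difficulty coding.
version: 1
fields:
  person_id: {kind: id, required: true}
  assessment_date: {kind: date, required: true}
  bathing: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  personal_hygiene: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  dressing_upper: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  dressing_lower: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  walking_indoors: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  walking_outdoors: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  locomotion: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  toilet_use: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  eating: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  bed_mobility: {kind: code, values: [0, 1, 2, 3, 4, 5, 6, 8]}
  decision_making: {kind: code, values: [0, 1, 2, 3, 4]}
  short_term_memory_ok: {kind: code, values: [0, 1]}
  making_self_understood: {kind: code, values: [0, 1, 2, 3, 4]}
  meal_preparation: {kind: code, values: [0, 1, 2]}
  ordinary_housework: {kind: code, values: [0, 1, 2]}
  phone_use: {kind: code, values: [0, 1, 2]}
  bladder_incontinence: {kind: code, values: [0, 1, 2, 3, 4, 5]}
  bowel_incontinence: {kind: code, values: [0, 1, 2, 3, 4, 5]}
  unstable_conditions: {kind: code, values: [0, 1]}
  caregiver_distress: {kind: code, values: [0, 1]}
  estimated_aide_minutes: {kind: minutes, required: false}
  estimated_homemaking_minutes: {kind: minutes, required: false}
  age: {kind: number, required: false}
  sex: {kind: category, values: [F, M, other], required: false}
  living_alone: {kind: code, values: [0, 1], required: false}
  setting:
    kind: category
    values: [community, retirement_home, supportive_housing, assisted_living]
    required: false
  on_waitlist_or_hold: {kind: code, values: [0, 1], required: false}
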