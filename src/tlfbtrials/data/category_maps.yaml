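# Default harmonization dictionaries: raw instrument categories -> binary flags.
# Each of the five trial instruments can override these per study; unmapped
# categories are a hard error, never silently coerced.
marital:                 # -> married_cohab
  married: true
  cohabitating: true
  separated: false
  divorced: false
  widowed: false
  never_married: false
employment:              # -> employed (full or part time)
  full_time: true
  part_time: true
  unemployed: false
  disabled: false
  retired: false
  student: false
  military: false
income:                  # ordinal household-income bands -> at/above $60k per year
  lt_20k: false
  20_40k: false
  40_60k: false
  60_80k: true
  80_100k: true
  gt_100k: true
thc_screen:              # urine drug screen -> thc_positive
  positive: true
  negative: false
race:                    # collapse to indicator buckets; small categories -> other
  white: white
  black: black
  mixed: other
  native_american: other
  asian_pacific: other
  other: other
education_years_threshold: 12    # -> education_12plus
cigarettes_per_day_threshold: 10 # -> smoker_10plus
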