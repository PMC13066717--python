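# Treatment-schedule presets for the five bundled multi-site AUD pharmacotherapy
# trial designs.  treatment_weeks is the on-medication period; titration/taper
# weeks are metadata (contained within treatment_weeks, not added to it).
combine:
  treatment_weeks: 16
  titration_weeks: 0
  taper_weeks: 0
horizant:
  treatment_weeks: 26
  titration_weeks: 1
  taper_weeks: 1
levetiracetam:
  treatment_weeks: 16
  titration_weeks: 4
  taper_weeks: 2
varenicline:
  treatment_weeks: 13
  titration_weeks: 1
  taper_weeks: 0
quetiapine:
  treatment_weeks: 12
  titration_weeks: 2
  taper_weeks: 1
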