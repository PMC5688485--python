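# Default readiness checklists: per intervention, the items that must ALL be
# observed at a facility on the day of assessment for it to count as ready.
# These defaults are editable package assumptions (the minimum drugs, tests
# and equipment needed to deliver each intervention); override with your own
# file to match a specific assessment instrument.
syphilis:
  - syphilis_test
  - syphilis_treatment
diabetes:
  - glucose_test
  - diabetes_drug
hypertensive_disorders:
  - bp_apparatus
  - antihypertensive
malaria:
  - malaria_diagnostic
  - antimalarial
pre_eclampsia:
  - bp_apparatus
  - urine_protein_test
  - magnesium_sulphate
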