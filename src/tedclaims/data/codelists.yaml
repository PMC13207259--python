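# Named diagnosis-code sets used by the rule-based TED algorithms.
# Entries are [system, code]; a trailing "*" marks a prefix wildcard
# (matched after dot-insensitive normalization).  These defaults are
# editable data: revise them freely without touching the engine.
hyperthyroidism:
  - [ICD-10-CM, "E05*"]
  - [ICD-9, "242*"]
exophthalmos:
  - [ICD-10-CM, "H05.2*"]
  - [ICD-9, "376.2*"]
  - [ICD-9, "376.3*"]
diplopia:
  - [ICD-10-CM, "H53.2"]
  - [ICD-9, "368.2"]
lid_retraction:
  - [ICD-10-CM, "H02.53*"]
  - [ICD-9, "374.41"]
strabismus:
  - [ICD-10-CM, "H49*"]
  - [ICD-10-CM, "H50*"]
  - [ICD-9, "378*"]
orbital_inflammation:
  - [ICD-10-CM, "H05.0*"]
  - [ICD-10-CM, "H05.1*"]
  - [ICD-9, "376.0*"]
  - [ICD-9, "376.1*"]
ocular_pain:
  - [ICD-10-CM, "H57.1*"]
  - [ICD-9, "379.91"]
keratoconjunctivitis:
  - [ICD-10-CM, "H16.2*"]
  - [ICD-9, "370.4*"]
eye_edema:
  - [ICD-10-CM, "H02.84*"]
  - [ICD-9, "374.82"]
visual_disturbance:
  - [ICD-10-CM, "H53.1*"]
  - [ICD-10-CM, "H53.8"]
  - [ICD-10-CM, "H53.9"]
  - [ICD-9, "368.8"]
  - [ICD-9, "368.9"]
scotoma:
  - [ICD-10-CM, "H53.4*"]
  - [ICD-9, "368.4*"]
vision_deficiency:
  - [ICD-10-CM, "H54*"]
  - [ICD-9, "369*"]
corneal_ulcer:
  - [ICD-10-CM, "H16.0*"]
  - [ICD-9, "370.0*"]
optic_neuropathy:
  - [ICD-10-CM, "H46*"]
  - [ICD-10-CM, "H47.0*"]
  - [ICD-9, "377.3*"]
periorbital_edema:
  - [ICD-10-CM, "H05.22*"]
  - [ICD-9, "376.33"]
eyelid_erythema:
  - [ICD-10-CM, "H01.8"]
  - [ICD-10-CM, "H02.85*"]
  - [ICD-9, "374.89"]
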