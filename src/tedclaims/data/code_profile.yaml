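# Default per-code occurrence profile for the synthetic linked cohort.
#
# `ted` gives the probability that a confirmed-TED patient has at least one
# claim with the code inside +/-90, +/-180 and +/-365 days of the index date
# (nested windows, so the three values are nondecreasing).  The first block
# reproduces the published frequencies among confirmed TED patients; where a
# code reaches the published top-20 list in only some windows, the missing
# window values are extrapolated with a 0.85 nested-window ratio.
#
# `nonted` defaults to 0.6x the TED values when omitted; TED-specific signs
# (e.g. exophthalmos H05.20) carry explicit near-zero non-TED values.
#
# The trailing block adds TED-related eye-sign codes at package-chosen
# frequencies so the rule algorithms have realistic inputs; these are
# defaults of the simulator, not published frequencies.
- {code: "99214", system: CPT, description: "Office/outpatient visit, established patient, moderate complexity", ted: [0.421, 0.525, 0.631], mean_repeats: 1.5}
- {code: "99213", system: CPT, description: "Office/outpatient visit, established patient, low complexity", ted: [0.374, 0.493, 0.615], mean_repeats: 1.5}
- {code: "E05.00", system: ICD-10-CM, description: "Thyrotoxicosis with diffuse goiter without thyrotoxic crisis", ted: [0.323, 0.371, 0.424]}
- {code: "36415", system: CPT, description: "Collection of venous blood by venipuncture", ted: [0.249, 0.327, 0.416], mean_repeats: 1.2}
- {code: "I10", system: ICD-10-CM, description: "Essential (primary) hypertension", ted: [0.237, 0.312, 0.394]}
- {code: "84443", system: CPT, description: "Thyroid stimulating hormone (TSH) test", ted: [0.190, 0.252, 0.326], mean_repeats: 1.2}
- {code: "99204", system: CPT, description: "Office/outpatient visit, new patient, moderate complexity", ted: [0.184, 0.254, 0.356]}
- {code: "80053", system: CPT, description: "Comprehensive metabolic panel (CMP)", ted: [0.165, 0.239, 0.327]}
- {code: "85025", system: CPT, description: "Complete blood count (CBC) with differential", ted: [0.163, 0.237, 0.327]}
- {code: "E03.9", system: ICD-10-CM, description: "Hypothyroidism, unspecified", ted: [0.153, 0.214, 0.284]}
- {code: "84439", system: CPT, description: "Free thyroxine (T4) test", ted: [0.147, 0.194, 0.253]}
- {code: "E78.5", system: ICD-10-CM, description: "Hyperlipidemia, unspecified", ted: [0.123, 0.181, 0.249]}
- {code: "99203", system: CPT, description: "Office/outpatient visit, new patient, low complexity", ted: [0.119, 0.183, 0.282]}
- {code: "H04.123", system: ICD-10-CM, description: "Dry eye syndrome of bilateral lacrimal glands", ted: [0.118, 0.142, 0.167]}
- {code: "92014", system: CPT, description: "Comprehensive eye examination, established patient", ted: [0.118, 0.154, 0.210]}
- {code: "80061", system: CPT, description: "Lipid panel", ted: [0.113, 0.177, 0.250]}
- {code: "E05.90", system: ICD-10-CM, description: "Thyrotoxicosis, unspecified without thyrotoxic crisis or storm", ted: [0.111, 0.143, 0.168]}
- {code: "92083", system: CPT, description: "Visual field examination, unilateral or bilateral", ted: [0.107, 0.126, 0.148]}
- {code: "92012", system: CPT, description: "Intermediate eye examination, established patient", ted: [0.106, 0.125, 0.147]}
- {code: "H05.20", system: ICD-10-CM, description: "Unspecified exophthalmos", ted: [0.101, 0.119, 0.140], nonted: [0.004, 0.005, 0.006]}
- {code: "Z00.00", system: ICD-10-CM, description: "Encounter for general adult medical examination without abnormal findings", ted: [0.127, 0.149, 0.225]}
- {code: "83036", system: CPT, description: "Glycosylated hemoglobin (HbA1c) test", ted: [0.122, 0.144, 0.201]}
- {code: "Z12.31", system: ICD-10-CM, description: "Encounter for screening mammogram for malignant neoplasm of breast", ted: [0.122, 0.144, 0.214]}
- {code: "Z23", system: ICD-10-CM, description: "Encounter for immunization", ted: [0.157, 0.184, 0.217]}
- {code: "Z79.899", system: ICD-10-CM, description: "Long term (current) use of other medications", ted: [0.141, 0.166, 0.195]}
# --- simulator-chosen TED eye-sign codes (not from the published top-20) ---
- {code: "H53.2", system: ICD-10-CM, description: "Diplopia", ted: [0.060, 0.080, 0.100], nonted: [0.018, 0.024, 0.030]}
- {code: "H02.531", system: ICD-10-CM, description: "Eyelid retraction, right upper eyelid", ted: [0.030, 0.040, 0.050], nonted: [0.002, 0.002, 0.003]}
- {code: "H05.243", system: ICD-10-CM, description: "Constant exophthalmos, bilateral", ted: [0.020, 0.030, 0.040], nonted: [0.001, 0.001, 0.002]}
- {code: "H16.223", system: ICD-10-CM, description: "Keratoconjunctivitis sicca, bilateral", ted: [0.040, 0.050, 0.070], nonted: [0.020, 0.025, 0.035]}
- {code: "H05.89", system: ICD-10-CM, description: "Other disorders of orbit", ted: [0.030, 0.040, 0.050], nonted: [0.004, 0.005, 0.006]}
- {code: "H05.10", system: ICD-10-CM, description: "Unspecified acute inflammation of orbit", ted: [0.015, 0.020, 0.025], nonted: [0.002, 0.003, 0.004]}
- {code: "H53.8", system: ICD-10-CM, description: "Other visual disturbances", ted: [0.020, 0.030, 0.040], nonted: [0.008, 0.012, 0.016]}
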