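# Study code dictionaries.
#
# The NDC and procedure codes below are synthetic but structurally valid
# placeholders (real DMT code lists are licensed supplements); edit this file
# or point the loader at your own copy to use production code sets.
# ICD-9-CM matching is by prefix on the dot-stripped code.

ndc:
  IFN:                      # interferon beta products (four formulations)
    - "50000000101"
    - "50000000102"
    - "50000000103"
    - "50000000104"
  GA:                       # glatiramer acetate
    - "50000000201"
  fingolimod:
    - "50000000301"
  natalizumab:
    - "50000000401"
  dalfampridine:
    - "50000000501"
  oral_corticosteroid:
    - "50000000601"
    - "50000000602"

procedures:
  IFN:
    - "J9001"
  GA:
    - "J9002"
  natalizumab:
    - "J9004"
  iv_corticosteroid:
    - "J9006"

icd9:
  ms:
    - "340"
  # Primary diagnoses that disqualify an outpatient visit + corticosteroid
  # pair from counting as a relapse (steroids given for another indication).
  exclusionary_primary:
    - "493"   # asthma
    - "274"   # gout
    - "714"   # rheumatoid arthritis
    - "364"   # uveitis
  symptoms:
    numbness: ["7820"]
    fatigue: ["7807"]
    bowel: ["5640", "7876"]
    headache: ["7840"]
    muscle_weakness: ["7282", "7811"]
    visual: ["368", "369"]
    bladder: ["5966", "7882"]
    dizziness: ["7804"]
    respiration: ["7860"]
    walking: ["7812", "7813"]
  comorbidities:
    depression: ["311", "2962", "2963"]
    diabetes: ["250"]
    dyslipidemia: ["272"]
    tobacco: ["3051"]
    cvd: ["410", "412", "428"]
  charlson:
    - category: myocardial_infarction
      prefixes: ["410", "412"]
      weight: 1
    - category: congestive_heart_failure
      prefixes: ["428"]
      weight: 1
    - category: diabetes
      prefixes: ["250"]
      weight: 1
    - category: renal_disease
      prefixes: ["585", "586"]
      weight: 2
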