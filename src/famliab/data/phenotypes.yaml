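# Phenotype definitions: ICD code prefixes per revision era.
# A representative subset mirroring national patient-register practice:
# the exposure trait (borderline personality disorder) plus outcomes
# covering the psychiatric / somatic / behavioral domains, a female-only
# phenotype and a cause-of-death-sourced one.
- name: bpd
  domain: psychiatric
  icd9: ["301D", "301J"]
  icd10: ["F60.3"]
  within_generation_only: true
- name: depressive_disorder
  domain: psychiatric
  icd9: ["311"]
  icd10: ["F32", "F33"]
  within_generation_only: true
- name: sleep_disorder
  domain: somatic
  icd9: ["307.4"]
  icd10: ["F51", "G47"]
- name: pcos
  domain: somatic
  icd9: ["256.4"]
  icd10: ["E28.2"]
  female_only: true
- name: suicide
  domain: behavioral
  icd9: ["E95"]
  icd10: ["X6", "X7", "X80", "X81", "X82", "X83", "X84"]
  cause_of_death_source: true
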