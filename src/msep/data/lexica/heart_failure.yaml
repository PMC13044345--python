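# Reconstruction lexicon for heart failure status (French).
condition: heart_failure
has_former: false
family_semantics: familial_means_unknown
keyword_patterns:
  - insuffisance cardiaque
  - décompensation cardiaque
  - défaillance cardiaque
  - insuffisant cardiaque
negation_cues:
  - pas de
  - pas d'
  - absence de
  - absence d'
  - aucun
  - aucune
  - sans
  - "non"
family_cues:
  - père
  - mère
  - familial
  - familiale
  - familiaux
  - famille
  - parents
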