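# Reconstruction lexicon for family history of cancer (French). The condition
# is itself familial: a family-context cue asserts presence.
condition: family_cancer
has_former: false
family_semantics: condition_is_familial
keyword_patterns:
  - cancer
  - néoplasie
  - tumeur
  - carcinome
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
  - antécédents familiaux
  - antécédent familial
  - père
  - mère
  - familial
  - familiale
  - familiaux
  - famille
  - frère
  - soeur
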