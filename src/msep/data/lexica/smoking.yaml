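# Reconstruction lexicon for smoking status (French). Editable starter set,
# not the original institutional rule file.
condition: smoking
has_former: true
family_semantics: familial_means_unknown
keyword_patterns:
  - tabac
  - tabagisme
  - tabagique
  - fumeur
  - fumeuse
  - cigarette
  - nicotine
negation_cues:
  - pas de
  - pas d'
  - absence de
  - absence d'
  - aucun
  - aucune
  - sans
  - "non"
  - jamais
cessation_cues:
  - sevré
  - sevrée
  - sevrage
  - arrêt
  - arrêté
  - stoppé
  - ancien
  - ancienne
  - ex-
relapse_cues:
  - reprise
  - repris
  - rechute
family_cues:
  - père
  - mère
  - familial
  - familiale
  - familiaux
  - famille
  - parents
  - frère
  - soeur
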