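# Verb-related grammatical category codebook (version 1).
# 16 categories: 5 syntactic, 11 bound-morphological.
# Noun-phrase structures (nouns, pronouns, determiners, noun adverbs and
# prepositions attached to nouns) are deliberately absent: verb coding is
# "verb-related", not a full verb phrase.
type: verb
categories:
  - {code: 1,  label: verb,                        sublevel: syntax}
  - {code: 2,  label: adverb,                      sublevel: syntax}
  - {code: 3,  label: preposition,                 sublevel: syntax}
  - {code: 4,  label: negative,                    sublevel: syntax}
  - {code: 5,  label: infinitive,                  sublevel: syntax}
  - {code: 6,  label: first_third_person_singular, sublevel: morphology}
  - {code: 7,  label: first_person_singular,       sublevel: morphology}
  - {code: 8,  label: third_person_singular,       sublevel: morphology}
  - {code: 9,  label: present_participle,          sublevel: morphology}
  - {code: 10, label: past_participle,             sublevel: morphology}
  - {code: 11, label: present_tense,               sublevel: morphology}
  - {code: 12, label: past_tense,                  sublevel: morphology}
  - {code: 13, label: modal,                       sublevel: morphology}
  - {code: 14, label: progressive,                 sublevel: morphology}
  - {code: 15, label: copula,                      sublevel: morphology}
  - {code: 16, label: auxiliary,                   sublevel: morphology}
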