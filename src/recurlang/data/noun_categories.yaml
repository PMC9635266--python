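# Noun-related grammatical category codebook (version 1).
# 14 categories: 10 syntactic, 4 bound-morphological.
type: noun
categories:
  - {code: 1,  label: common_noun,   sublevel: syntax}
  - {code: 2,  label: proper_noun,   sublevel: syntax}
  - {code: 3,  label: pronoun,       sublevel: syntax}
  - {code: 4,  label: determiner,    sublevel: syntax}
  - {code: 5,  label: adjective,     sublevel: syntax}
  - {code: 6,  label: adverb,        sublevel: syntax}
  - {code: 7,  label: gerund,        sublevel: syntax}
  - {code: 8,  label: wh_question,   sublevel: syntax}
  - {code: 9,  label: number,        sublevel: syntax}
  - {code: 10, label: preposition,   sublevel: syntax}
  - {code: 11, label: plural,        sublevel: morphology}
  - {code: 12, label: possessive,    sublevel: morphology}
  - {code: 13, label: superlative,   sublevel: morphology}
  - {code: 14, label: comparative,   sublevel: morphology}
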