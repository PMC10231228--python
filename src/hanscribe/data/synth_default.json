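{
  "n_docs_per_class": 200,
  "words_per_sentence": [8.0, 2.0],
  "n_distractors": 200,
  "ctrl": {
    "filler_rate": 0.01,
    "pronoun_substitution_rate": 0.02,
    "seed_word_coverage": 0.8,
    "sentence_count": [11.0, 2.0]
  },
  "ad": {
    "filler_rate": 0.15,
    "pronoun_substitution_rate": 0.30,
    "seed_word_coverage": 0.3,
    "sentence_count": [6.0, 1.5]
  }
}
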