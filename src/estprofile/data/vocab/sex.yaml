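# Default sex vocabulary (4 categories).
axis: sex
unknown_label: uncharacterized
terms:
  - term: female
    synonyms: [f, females]
  - term: male
    synonyms: [m, males]
  - term: mixed
    synonyms: [mixed sex, male and female, pooled]
  - term: not determined
    synonyms: [nd, undetermined]
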