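# Default Bombyx mori strain vocabulary (10 strains).
axis: strain
unknown_label: uncharacterized
terms:
  - term: Dazao
    synonyms: [p50, P50, Dazao (P50), da zao]
  - term: C108
    synonyms: [c 108]
  - term: Nistari
    synonyms: []
  - term: Jingsong
    synonyms: [jing song]
  - term: Haoyue
    synonyms: [hao yue]
  - term: Qiufeng
    synonyms: [qiu feng]
  - term: Baiyu
    synonyms: [bai yu]
  - term: "306"
    synonyms: []
  - term: "54A"
    synonyms: [54 a]
  - term: N4
    synonyms: []
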