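# Default Bombyx mori tissue vocabulary (28 canonical tissue/organ types).
# Order is biologically grouped and drives axis order in figures.
axis: tissue
unknown_label: uncharacterized
terms:
  - term: ovary
    synonyms: [ovaries, ovarian tissue]
  - term: testis
    synonyms: [testes, testicle]
  - term: silk gland
    synonyms: [silkgland, silk glands]
  - term: anterior silk gland
    synonyms: [ASG]
  - term: middle silk gland
    synonyms: [MSG, median silk gland]
  - term: posterior silk gland
    synonyms: [PSG]
  - term: wing disk
    synonyms: [wing disc, wing imaginal disc, wing imaginal disk]
  - term: fat body
    synonyms: [fatbody, fat bodies]
  - term: microbe-infected fat body
    synonyms: [infected fat body, bacteria-infected fat body]
  - term: pheromone gland
    synonyms: [sex pheromone gland]
  - term: prothoracic gland
    synonyms: [PG]
  - term: midgut
    synonyms: [mid-gut, mid gut]
  - term: hindgut
    synonyms: [hind-gut]
  - term: head
    synonyms: [heads]
  - term: brain
    synonyms: [cephalic ganglion]
  - term: malpighian tubule
    synonyms: [malpighian tubules, malphigian tubule]
  - term: epidermis
    synonyms: [integument, skin]
  - term: hemocyte
    synonyms: [haemocyte, hemocytes, blood cell]
  - term: trachea
    synonyms: [tracheae]
  - term: muscle
    synonyms: [body wall muscle]
  - term: antenna
    synonyms: [antennae]
  - term: compound eye
    synonyms: [eye]
  - term: maxillary galea
    synonyms: [maxilla]
  - term: corpus allatum
    synonyms: [corpora allata]
  - term: BmNPV-infected ovary
    synonyms: [virus-infected ovary, NPV-infected ovary]
  - term: egg
    synonyms: [eggs, HCl-treated egg]
  - term: whole body
    synonyms: [whole larva, whole animal, entire body]
  - term: uncharacterized tissue
    synonyms: [unclassified tissue]
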