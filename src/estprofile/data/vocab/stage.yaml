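# Default Bombyx mori developmental-stage vocabulary (31 canonical stages),
# ordered by development; figure axes follow this order.
axis: stage
unknown_label: uncharacterized
terms:
  - term: egg
    synonyms: [eggs, fertilized egg]
  - term: diapause egg
    synonyms: [diapausing egg]
  - term: embryo
    synonyms: [embryonic stage]
  - term: 1st instar larva
    synonyms: [first instar, instar 1]
  - term: 2nd instar larva
    synonyms: [second instar, instar 2]
  - term: 3rd instar larva
    synonyms: [third instar, instar 3]
  - term: 4th instar larva
    synonyms: [fourth instar, instar 4]
  - term: 4th instar day 2 larva
    synonyms: [4th instar day 2, fourth instar day 2]
  - term: 4th instar day 3 larva
    synonyms: [4th instar day 3]
  - term: 4th instar molting larva
    synonyms: [4th molt, fourth molting]
  - term: 5th instar larva
    synonyms: [fifth instar, instar 5]
  - term: 5th instar day 1 larva
    synonyms: [5th instar day 1]
  - term: 5th instar day 2 larva
    synonyms: [5th instar day 2]
  - term: 5th instar day 3 larva
    synonyms: [5th instar day 3, fifth instar day 3, day 3 of 5th instar]
  - term: 5th instar day 4 larva
    synonyms: [5th instar day 4]
  - term: 5th instar day 5 larva
    synonyms: [5th instar day 5]
  - term: 5th instar day 6 larva
    synonyms: [5th instar day 6]
  - term: 5th instar to spinning larva
    synonyms: [5th instar-spinning, mixture of 5th instar to spinning]
  - term: wandering larva
    synonyms: [wandering stage]
  - term: spinning larva
    synonyms: [spinning, spinning stage]
  - term: prepupa
    synonyms: [pre-pupa]
  - term: pupa
    synonyms: [pupal stage, pupae]
  - term: pupa day 1
    synonyms: [day 1 pupa]
  - term: pupa day 2
    synonyms: [day 2 pupa]
  - term: pupa day 3
    synonyms: [day 3 pupa]
  - term: pupa day 4
    synonyms: [day 4 pupa]
  - term: pupa day 5
    synonyms: [day 5 pupa]
  - term: pupa day 7
    synonyms: [day 7 pupa]
  - term: pharate adult
    synonyms: [eclosion stage]
  - term: adult
    synonyms: [moth, imago]
  - term: mixed stages
    synonyms: [mixed stage, pooled stages]
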