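nouns:
- form: oksham
  class: 1
  frequency: 32
  object: dog
  stress: stress1
  uniphones:
  - '#o'
  - k
  - ʃ
  - a
  - m#
- form: luobar
  class: 1
  frequency: 23
  object: cat
  stress: stress1
  uniphones:
  - '#l'
  - u
  - o
  - b
  - a
  - r#
- form: anhatar
  class: 1
  frequency: 16
  object: chicken
  stress: stress1
  uniphones:
  - '#a'
  - n
  - h
  - a
  - t
  - a
  - r#
- form: simad
  class: 1
  frequency: 11
  object: horse
  stress: stress1
  uniphones:
  - '#s'
  - i
  - m
  - a
  - d#
- form: nechran
  class: 1
  frequency: 8
  object: pig
  stress: stress1
  uniphones:
  - '#n'
  - e
  - x
  - r
  - a
  - n#
- form: kekunam
  class: 1
  frequency: 6
  object: mouse
  stress: stress1
  uniphones:
  - '#k'
  - e
  - k
  - u
  - n
  - a
  - m#
- form: kitsogis
  class: 1
  frequency: 4
  object: sheep
  stress: stress1
  uniphones:
  - '#k'
  - i
  - ts
  - o
  - g
  - i
  - s#
- form: magril
  class: 1
  frequency: 3
  object: rabbit
  stress: stress1
  uniphones:
  - '#m'
  - a
  - g
  - r
  - i
  - l#
- form: kanjur
  class: 2
  frequency: 32
  object: rose
  stress: stress3/4
  uniphones:
  - '#k'
  - a
  - n
  - j
  - u
  - r#
- form: ennovis
  class: 2
  frequency: 23
  object: sunflower
  stress: stress3/4
  uniphones:
  - '#e'
  - n
  - n
  - o
  - v
  - i
  - s#
- form: ruis
  class: 2
  frequency: 16
  object: tulip
  stress: stress3/4
  uniphones:
  - '#r'
  - u
  - i
  - s#
- form: lopranik
  class: 2
  frequency: 11
  object: orchid
  stress: stress3/4
  uniphones:
  - '#l'
  - o
  - p
  - r
  - a
  - n
  - i
  - k#
- form: aftong
  class: 2
  frequency: 8
  object: dandelion
  stress: stress3/4
  uniphones:
  - '#a'
  - f
  - t
  - o
  - ŋ#
- form: palneng
  class: 2
  frequency: 6
  object: poppy
  stress: stress3/4
  uniphones:
  - '#p'
  - a
  - l
  - n
  - e
  - ŋ#
- form: tivitkal
  class: 2
  frequency: 4
  object: daisy
  stress: stress3/4
  uniphones:
  - '#t'
  - i
  - v
  - i
  - t
  - k
  - a
  - l#
- form: meromer
  class: 2
  frequency: 3
  object: forgetmenot
  stress: stress3/4
  uniphones:
  - '#m'
  - e
  - r
  - o
  - m
  - e
  - r#
- form: anveal
  class: 3
  frequency: 32
  object: car
  stress: stress2
  uniphones:
  - '#a'
  - n
  - v
  - e
  - a
  - l#
- form: psondew
  class: 3
  frequency: 23
  object: chair
  stress: stress2
  uniphones:
  - '#p'
  - s
  - o
  - n
  - d
  - e
  - w#
- form: hatrumir
  class: 3
  frequency: 16
  object: banana
  stress: stress2
  uniphones:
  - '#h'
  - a
  - t
  - r
  - u
  - m
  - i
  - r#
- form: kilal
  class: 3
  frequency: 11
  object: lake
  stress: stress2
  uniphones:
  - '#k'
  - i
  - l
  - a
  - l#
- form: repis
  class: 3
  frequency: 8
  object: sewingmachine
  stress: stress2
  uniphones:
  - '#r'
  - e
  - p
  - i
  - s#
- form: tokran
  class: 3
  frequency: 6
  object: kite
  stress: stress2
  uniphones:
  - '#t'
  - o
  - k
  - r
  - a
  - n#
- form: istefur
  class: 3
  frequency: 4
  object: fence
  stress: stress2
  uniphones:
  - '#i'
  - s
  - t
  - e
  - f
  - u
  - r#
- form: merkatim
  class: 3
  frequency: 3
  object: foot
  stress: stress2
  uniphones:
  - '#m'
  - e
  - r
  - k
  - a
  - t
  - i
  - m#
- form: jajosan
  class: 4
  frequency: 32
  object: airplane
  stress: stress3/4
  uniphones:
  - '#j'
  - a
  - j
  - o
  - s
  - a
  - n#
- form: serim
  class: 4
  frequency: 23
  object: shelf
  stress: stress3/4
  uniphones:
  - '#s'
  - e
  - r
  - i
  - m#
- form: erkefal
  class: 4
  frequency: 16
  object: apple
  stress: stress3/4
  uniphones:
  - '#e'
  - r
  - k
  - e
  - f
  - a
  - l#
- form: vimeros
  class: 4
  frequency: 11
  object: mountain
  stress: stress3/4
  uniphones:
  - '#v'
  - i
  - m
  - e
  - r
  - o
  - s#
- form: burbad
  class: 4
  frequency: 8
  object: flatiron
  stress: stress3/4
  uniphones:
  - '#b'
  - u
  - r
  - b
  - a
  - d#
- form: ksoster
  class: 4
  frequency: 6
  object: ball
  stress: stress3/4
  uniphones:
  - '#k'
  - s
  - o
  - s
  - t
  - e
  - r#
- form: natrul
  class: 4
  frequency: 4
  object: umbrella
  stress: stress3/4
  uniphones:
  - '#n'
  - a
  - t
  - r
  - u
  - l#
- form: rutonak
  class: 4
  frequency: 3
  object: ear
  stress: stress3/4
  uniphones:
  - '#r'
  - u
  - t
  - o
  - n
  - a
  - k#
meaning_sets:
  1:
  - D1meaning
  2:
  - D2meaning
  3:
  - D3meaning
  4:
  - D3meaning
form_sets:
  1:
  - D1form
  - O1form
  - O2form
  2:
  - D3form
  - O1form
  - O3form
  3:
  - D2form
  - O2form
  - O3form
  4:
  - D3form
  - O1form
  - O3form
premarkers:
  1: ima
  2: imo
  3: ime
  4: imi
postmarkers:
  1: ove/ovu
  2: ira/ire
  3: agi/ago
  4: epo/epa
unspecific_premarker: imo
unspecific_postmarker: agi
phone_table:
- - sh
  - ʃ
- - ng
  - ŋ
- - ch
  - x
carrier_phrases:
- unta boltohe
- ena dikanhe
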