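# Synthetic reference scaffolds with annotated catalytic positions.
# Substitute real enzyme sequences (AnEH/StEH/AgAD1/ReLEH...) via
# ReferenceSet.from_files with the same schema.
references:
- id: refG5a
  family: abEH
  group: group5
  nterm: true
  positions:
    nucleophile: 231
    base: 399
    tyrosine: 279
    acid_A: 359
    acid_B: 324
- id: refG5b
  family: abEH
  group: group5
  nterm: true
  positions:
    nucleophile: 231
    base: 399
    tyrosine: 279
    acid_A: 359
    acid_B: 324
- id: refG8a
  family: abEH
  group: group8
  nterm: false
  positions:
    nucleophile: 107
    base: 275
    tyrosine: 155
    acid_A: 235
    acid_B: 200
- id: refG8b
  family: abEH
  group: group8
  nterm: false
  positions:
    nucleophile: 107
    base: 275
    tyrosine: 155
    acid_A: 235
    acid_B: 200
- id: refG6dh
  family: dehalogenase
  group: group6
  nterm: false
  positions:
    nucleophile: 107
    base: 275
    tyrosine: 155
    acid_A: 235
    acid_B: 200
- id: refLEHa1
  family: LEH
  group: lehA
  releh_like: true
  positions:
    asp1: 101
    arg: 99
    asp2: 132
    water1: 53
    water2: 55
    sel_80: 80
    sel_114: 114
    sel_116: 116
- id: refLEHa2
  family: LEH
  group: lehA
  releh_like: false
  positions:
    asp1: 101
    arg: 99
    asp2: 132
    water1: 53
    water2: 55
- id: refLEHb1
  family: LEH
  group: lehB
  releh_like: false
  positions:
    asp1: 101
    arg: 99
    asp2: 132
    water1: 53
    water2: 55
- id: refLEHb2
  family: LEH
  group: lehB
  releh_like: false
  positions:
    asp1: 101
    arg: 99
    asp2: 132
    water1: 53
    water2: 55
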