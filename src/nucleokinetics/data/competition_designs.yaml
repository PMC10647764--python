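# Competitive reconstitution designs: constant total octamer mass per
# reaction, split between canonical (H2A) and H2A.Z-containing octamers
# over six gradients, on 3 ug of 147-bp 601 template DNA in 60 uL.
# Masses in ug; time is the first-step dialysis duration in hours.
designs:
  - total_protein_mass: 2.4
    dna_mass: 3.0
    volume: 60.0
    time: 16.0
    gradients:
      - [0.0, 2.4]
      - [0.48, 1.92]
      - [0.96, 1.44]
      - [1.44, 0.96]
      - [1.92, 0.48]
      - [2.4, 0.0]
  - total_protein_mass: 3.0
    dna_mass: 3.0
    volume: 60.0
    time: 16.0
    gradients:
      - [0.0, 3.0]
      - [0.6, 2.4]
      - [1.2, 1.8]
      - [1.8, 1.2]
      - [2.4, 0.6]
      - [3.0, 0.0]
  - total_protein_mass: 3.6
    dna_mass: 3.0
    volume: 60.0
    time: 16.0
    gradients:
      - [0.0, 3.6]
      - [0.72, 2.88]
      - [1.44, 2.16]
      - [2.16, 1.44]
      - [2.88, 0.72]
      - [3.6, 0.0]
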