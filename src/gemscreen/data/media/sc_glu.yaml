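# Synthetic-complete glucose-limited medium template: minimal salts plus
# supplemented amino acids and nucleobases.  The exact composition is a
# run input -- edit this file to the screen design being emulated and
# map keys to each model's exchange ids (see min_glu.yaml).
name: SC-Glu
uptake_bounds:
  glucose: [-10.0, 1000.0]
  ammonium: [-1000.0, 1000.0]
  oxygen: [-1000.0, 1000.0]
  phosphate: [-1000.0, 1000.0]
  sulphate: [-1000.0, 1000.0]
  # supplemented organic components (open at a permissive uptake):
  # L-alanine: [-10.0, 1000.0]
  # ...one entry per supplemented amino acid / nucleobase...
supplements: {}
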