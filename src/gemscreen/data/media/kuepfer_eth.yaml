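# Kuepfer-style defined medium template with ethanol as sole carbon
# source; differs from the other kuepfer_* media only in the carbon key.
# Edit keys to match each model's exchange ids (see min_glu.yaml).
name: Kuepfer-Eth
uptake_bounds:
  ethanol: [-10.0, 1000.0]
  ammonium: [-1000.0, 1000.0]
  oxygen: [-1000.0, 1000.0]
  phosphate: [-1000.0, 1000.0]
  sulphate: [-1000.0, 1000.0]
supplements: {}
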