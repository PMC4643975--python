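# Minimal glucose-limited medium template.
#
# Component keys are resolved against each model in order: exchange
# reaction id, exchanged metabolite id, ChEBI identifier.  Published
# models use incompatible exchange ids, so edit the keys (or add a
# per-model supplements entry) to match the model being simulated.
# Uptake is a negative lower bound; -1000 means unconstrained.
name: Min-Glu
uptake_bounds:
  glucose: [-10.0, 1000.0]
  ammonium: [-1000.0, 1000.0]
  oxygen: [-1000.0, 1000.0]
  phosphate: [-1000.0, 1000.0]
  sulphate: [-1000.0, 1000.0]
supplements:
  # models that cannot grow on the plain minimal medium get extra open
  # exchanges here, e.g.:
  # iMM904bs: [iron]
  {}
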