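# Two-level habitat vocabulary. Level 1 is closed; level-2 terms are the
# categories used in the habitat-distribution summaries and are extendable.
aquatic:
  - marine
  - freshwater
  - sediment
terrestrial:
  - soil
engineered:
  - bioreactor
host_associated:
  - plants
  - arthropoda
  - mammals
  - annelida
  - lichen
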