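# Defined minimal medium template in the Verduyn style: glucose, ammonium,
# phosphate, sulfate, oxygen and trace components. The exchange-reaction ids
# below follow this package's naming; EDIT THEM to match your model's ids
# and verify the component list against the medium recipe you use — trace
# element and vitamin exchanges differ between reconstructions.
name: verduyn_minimal
description: defined minimal medium (glucose/ammonium/salts), user-verifiable
bounds:
  EX_glc: [-10.0, 1000.0]
  EX_nh4: [-1000.0, 1000.0]
  EX_pi: [-1000.0, 1000.0]
  EX_so4: [-1000.0, 1000.0]
  EX_o2: [-1000.0, 1000.0]
  EX_h2o: [-1000.0, 1000.0]
  EX_h: [-1000.0, 1000.0]
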