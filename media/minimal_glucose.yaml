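name: minimal_glucose
description: >
  Minimal medium for the synthetic study models: glucose as the sole
  carbon source at a 10 mmol/gDW/h uptake bound. Exchange reactions not
  listed here are closed for uptake when the medium is applied.
bounds:
  EX_glc: [-10.0, 1000.0]
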