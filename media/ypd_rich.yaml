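# Rich (YPD-like) medium template: glucose plus amino acids, nucleobases
# and vitamins as a configurable list — a rich medium's in-silico content
# is a modelling choice, not a property of the model, so the compound list
# lives here and not in code. Uptake bounds for most components are left
# generous; myo-inositol is the exception, set to the small abundance
# value 0.001 mmol/gDW/h commonly used when no measurement is available.
# EDIT exchange ids to match your model.
name: ypd_rich
description: rich medium template (glucose + amino acids + nucleobases + vitamins)
bounds:
  EX_glc: [-10.0, 1000.0]
  EX_nh4: [-1000.0, 1000.0]
  EX_pi: [-1000.0, 1000.0]
  EX_so4: [-1000.0, 1000.0]
  EX_o2: [-1000.0, 1000.0]
  EX_h2o: [-1000.0, 1000.0]
  EX_h: [-1000.0, 1000.0]
  EX_ala: [-1.0, 1000.0]
  EX_arg: [-1.0, 1000.0]
  EX_asn: [-1.0, 1000.0]
  EX_asp: [-1.0, 1000.0]
  EX_cys: [-1.0, 1000.0]
  EX_gln: [-1.0, 1000.0]
  EX_glu: [-1.0, 1000.0]
  EX_gly: [-1.0, 1000.0]
  EX_his: [-1.0, 1000.0]
  EX_ile: [-1.0, 1000.0]
  EX_leu: [-1.0, 1000.0]
  EX_lys: [-1.0, 1000.0]
  EX_met: [-1.0, 1000.0]
  EX_phe: [-1.0, 1000.0]
  EX_pro: [-1.0, 1000.0]
  EX_ser: [-1.0, 1000.0]
  EX_thr: [-1.0, 1000.0]
  EX_trp: [-1.0, 1000.0]
  EX_tyr: [-1.0, 1000.0]
  EX_val: [-1.0, 1000.0]
  EX_ade: [-0.5, 1000.0]
  EX_ura: [-0.5, 1000.0]
  EX_ribo: [-0.5, 1000.0]
  EX_inost: [-0.001, 1000.0]
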