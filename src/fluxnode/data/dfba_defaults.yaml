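# Batch-growth simulation defaults for the four cultured cell lines:
# counted initial densities (cells in the delimited area) and the medium
# glucose at seeding (200 mg/dl = 11.1 mM), simulated over 72 h.
glucose_mg_dl: 200.0
glucose_mM: 11.1
horizon_h: 72.0
dt_h: 1.0
initial_cells:
  MCF7: 37
  T47D: 31
  MDAMB231: 30
  MDAMB468: 58
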