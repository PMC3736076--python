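# Alternate compliance ranges: identical to the default table except for
# the wider log K_HSA (upper 1.5) and log B/B (upper 1.2) bounds that
# appear in per-property recommendations.
ranges:
  s_mol: {lower: 300.0, upper: 1000.0}
  s_mol_hfob: {lower: 0.0, upper: 750.0}
  v_mol: {lower: 500.0, upper: 2000.0}
  log_s_wat: {lower: -6.0, upper: 0.5}
  log_k_hsa: {lower: -1.5, upper: 1.5}
  log_bb: {lower: -3.0, upper: 1.2}
  bip_caco2: {lower: 25.0, upper: 500.0}
  mdck: {lower: 25.0, upper: 500.0}
  ind_coh: {lower: 0.0, upper: 0.05}
  glob: {lower: 0.75, upper: 0.95}
  qp_polrz: {lower: 13.0, upper: 70.0}
  log_herg: {lower: -5.0}
  log_kp: {lower: -8.0, upper: -1.0}
  n_metab: {lower: 1, upper: 8}
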