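# Default compliance ranges: the interval spanned by 95% of known drugs
# for each descriptor.  A compound's #stars is the number of descriptors
# falling strictly outside these closed intervals.  One-sided entries
# give a single bound (log_herg: values below -5 flag cardiotoxicity
# concern).  Caco-2 has no published two-sided 95% range; 25-500 nm/s is
# adopted by analogy with MDCK.  Override any entry via a user config.
ranges:
  s_mol: {lower: 300.0, upper: 1000.0}        # A^2
  s_mol_hfob: {lower: 0.0, upper: 750.0}      # A^2
  v_mol: {lower: 500.0, upper: 2000.0}        # A^3
  log_s_wat: {lower: -6.0, upper: 0.5}
  log_k_hsa: {lower: -1.5, upper: 1.2}
  log_bb: {lower: -3.0, upper: 1.0}
  bip_caco2: {lower: 25.0, upper: 500.0}      # nm/s (adopted, see above)
  mdck: {lower: 25.0, upper: 500.0}           # nm/s
  ind_coh: {lower: 0.0, upper: 0.05}
  glob: {lower: 0.75, upper: 0.95}
  qp_polrz: {lower: 13.0, upper: 70.0}        # A^3
  log_herg: {lower: -5.0}                     # concern below -5
  log_kp: {lower: -8.0, upper: -1.0}
  n_metab: {lower: 1, upper: 8}
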