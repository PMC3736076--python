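# Default SD-tag schema: canonical descriptor name -> accepted SD-tag
# aliases, first match wins.  Ships with the common QikProp export names
# plus generic fallbacks; exports differ between versions, so the whole
# table is user-overridable.  kind: real | integer | ordinal.
# hba/hbd are declared real because some predictors export fractional
# hydrogen-bond counts; those are used as-is for compliance scoring.
descriptors:
  mw:          {aliases: ["mol MW", "MW", "mw"], kind: real}
  log_p:       {aliases: ["QPlogPo/w", "logP", "log_p", "LogP"], kind: real}
  hba:         {aliases: ["accptHB", "HBA", "hba"], kind: real}
  hbd:         {aliases: ["donorHB", "HBD", "hbd"], kind: real}
  nrb:         {aliases: ["#rotor", "NRB", "nrb", "RotatableBonds"], kind: integer}
  s_mol:       {aliases: ["SASA", "s_mol"], kind: real}
  s_mol_hfob:  {aliases: ["FOSA", "s_mol_hfob"], kind: real}
  v_mol:       {aliases: ["volume", "v_mol", "Volume"], kind: real}
  log_s_wat:   {aliases: ["QPlogS", "logS", "log_s_wat"], kind: real}
  ci_log_s_wat: {aliases: ["CIQPlogS", "ci_log_s_wat"], kind: real}
  log_k_hsa:   {aliases: ["QPlogKhsa", "log_k_hsa"], kind: real}
  log_bb:      {aliases: ["QPlogBB", "log_bb", "logBB"], kind: real}
  bip_caco2:   {aliases: ["QPPCaco", "Caco2", "bip_caco2"], kind: real}
  mdck:        {aliases: ["QPPMDCK", "MDCK", "mdck"], kind: real}
  ind_coh:     {aliases: ["IndCoh", "ind_coh"], kind: real}
  glob:        {aliases: ["glob", "Glob", "globularity"], kind: real}
  qp_polrz:    {aliases: ["QPpolrz", "qp_polrz"], kind: real}
  log_herg:    {aliases: ["QPlogHERG", "log_herg", "logHERG"], kind: real}
  log_kp:      {aliases: ["QPlogKp", "log_kp", "logKp"], kind: real}
  n_metab:     {aliases: ["#metab", "n_metab", "metab"], kind: integer}
  jm:          {aliases: ["Jm", "jm"], kind: real}
  percent_hoa: {aliases: ["PercentHumanOralAbsorption", "percent_hoa"], kind: real}
  qual_hoa:    {aliases: ["HumanOralAbsorption", "qual_hoa"], kind: ordinal}
  cns:         {aliases: ["CNS", "cns"], kind: ordinal}
  stars:       {aliases: ["#stars", "stars"], kind: integer}
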