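# Excitonic parameter bundle for the heptameric LH2 of Mch. purpuratum.
# provenance: "input" marks values transcribed from the published MD/QM
# analysis of this complex; "default" marks package defaults standing in for
# parameters that were not printed and must be overridden for quantitative use.
name: LH2purp
n_units: 7
site_energies:      # cm^-1, Qy
  alpha: 13724.0
  beta: 13630.0
  B800: 13634.0
couplings:          # cm^-1
  inter_dimer: 166.0
  b800_b800: 10.0
  intra_dimer: 220.0
  alpha_alpha: -40.0
  beta_beta: -15.0
  inter_ring: 25.0
ct:                 # cm^-1; effective one-CT-per-pair parameters
  energy: 15300.0
  intra_coupling: 600.0
  inter_coupling: 250.0
provenance:
  site_energies.alpha: input
  site_energies.beta: input
  site_energies.B800: input
  couplings.inter_dimer: input
  couplings.b800_b800: input
  couplings.intra_dimer: default
  couplings.alpha_alpha: default
  couplings.beta_beta: default
  couplings.inter_ring: default
  ct.energy: default
  ct.intra_coupling: default
  ct.inter_coupling: default
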