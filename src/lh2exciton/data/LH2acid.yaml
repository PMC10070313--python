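# Excitonic parameter bundle for the nonameric LH2 of Rbl. acidophilus
# (strain 10050).  See LH2purp.yaml for the provenance convention.
name: LH2acid
n_units: 9
site_energies:      # cm^-1, Qy
  alpha: 13527.0
  beta: 13556.0
  B800: 13783.0
couplings:          # cm^-1
  inter_dimer: 298.0
  b800_b800: 30.0
  intra_dimer: 240.0
  alpha_alpha: -50.0
  beta_beta: -45.0
  inter_ring: 30.0
ct:                 # cm^-1; effective one-CT-per-pair parameters
  energy: 15300.0
  intra_coupling: 450.0
  inter_coupling: 800.0
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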