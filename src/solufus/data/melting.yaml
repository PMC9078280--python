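# Fast-scanning-calorimetry melting properties shipped with the package.
# T_fus extrapolated to zero heating rate; dH_fus from the mass-proportional
# melting-peak areas.  Uncertainties are symmetric expanded uncertainties.
melting_properties:
- substance: l-alanine
  T_fus_K: 608.0
  u_T_fus_K: 9.0
  dH_fus_J_per_mol: 22000.0
  u_dH_fus_J_per_mol: 5000.0
- substance: glycine
  T_fus_K: 569.0
  u_T_fus_K: 7.0
  dH_fus_J_per_mol: 21000.0
  u_dH_fus_J_per_mol: 4000.0
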