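# PC-SAFT pure-component parameters for the aqueous amino-acid systems
# shipped with this package, plus the binary interaction parameters to water.
# All components use the 2B association scheme (one donor + one acceptor site).
# Units: sigma in angstrom, u_k and eps_assoc_k in kelvin, molar_mass in g/mol.
# Water uses the three-term exponential temperature-dependent segment diameter
#   sigma(T) = c0 + c1*exp(c2*T) + c3*exp(c4*T).
# kij(T) = kij_ref + kij_slope*(T - 298.15 K); the l-alanine/water pair carries
# a linear temperature dependence, the glycine/water pair does not.
components:
- id: glycine
  molar_mass: 75.1
  m_seg: 4.8495
  sigma: 2.3270
  u_k: 216.96
  eps_assoc_k: 2598.06
  kappa_assoc: 0.0393
  n_sites: 2B
- id: l-alanine
  molar_mass: 89.1
  m_seg: 5.4647
  sigma: 2.5222
  u_k: 287.59
  eps_assoc_k: 3176.60
  kappa_assoc: 0.0819
  n_sites: 2B
- id: water
  molar_mass: 18.015
  m_seg: 1.2047
  sigma:
    c0: 2.7927
    c1: 10.11
    c2: -0.01775
    c3: -1.417
    c4: -0.01146
  u_k: 353.94
  eps_assoc_k: 2425.67
  kappa_assoc: 0.0451
  n_sites: 2B
binary_interactions:
- pair: [glycine, water]
  kij_ref: -0.0585
  kij_slope: 0.0
- pair: [l-alanine, water]
  kij_ref: -0.0612
  kij_slope: 2.91e-4
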