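"""Physical constants and fixed unit conventions.

All equation-of-state internals are SI: segment diameters are converted from
angstrom to metre once, at the parameter boundary; number densities are
molecules per cubic metre.  Parameter files and user-facing interfaces keep
the units the thermodynamic literature prints: angstrom for sigma, kelvin for
energy parameters (u/kB, eps/kB), g/mol for molar masses.
"""

KB = 1.380649e-23
"""Boltzmann constant, J/K (exact, SI 2019)."""

NA = 6.02214076e23
"""Avogadro constant, 1/mol (exact, SI 2019)."""

R_GAS = 8.314
"""Molar gas constant, J/(mol K), at the precision used throughout."""

ANGSTROM = 1.0e-10
"""One angstrom in metres."""

M_WATER = 18.015
"""Molar mass of water, g/mol."""

P_ATM = 101325.0
"""Standard atmospheric pressure, Pa; default pressure for all liquid-phase work."""

T_REF_KIJ = 298.15
"""Reference temperature for binary-interaction parameters, K."""

ETA_MAX = 0.7405
"""Close-packing bound on the segment packing fraction."""
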