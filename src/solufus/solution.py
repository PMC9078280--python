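"""Aqueous-solution properties: concentration scales, activity and osmotic
coefficients.

Activity coefficients are on the mole-fraction scale with the pure
hypothetical liquid at the same T and P as reference:

    gamma_i(T, P, x) = phi_i(T, P, x) / phi_0i(T, P, pure liquid i)

so gamma_i -> 1 as x_i -> 1 by construction.  For a solid solute below its
melting point the reference is the subcooled liquid, taken as the
highest-density root of the equation of state.  The osmotic coefficient is
the solvent-centric measure

    Phi = -ln(a_w) / (M_w m),     a_w = x_w gamma_w

with M_w the water molar mass in kg/mol and m the solute molality.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .components import ParameterSet
from .constants import M_WATER, P_ATM
from .errors import DomainError, ReferenceStateError, DensitySolveError
from .pcsaft import ln_fugacity_coefficients

WATER = "water"


def molality_to_mole_fraction(molality: float, molar_mass_water: float = M_WATER) -> float:
    """Solute mole fraction from molality (mol solute per kg water)."""
    m = np.asarray(molality, dtype=float)
    if np.any(m < 0):
        raise DomainError(f"molality must be nonnegative, got {molality}")
    out = m / (m + 1000.0 / molar_mass_water)
    return float(out) if out.ndim == 0 else out


def mole_fraction_to_molality(x: float, molar_mass_water: float = M_WATER) -> float:
    """Inverse of :func:`molality_to_mole_fraction`; exact round trip."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0) or np.any(xa >= 1):
        raise DomainError(f"mole fraction must lie in [0, 1), got {x}")
    out = 1000.0 / molar_mass_water * xa / (1.0 - xa)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=2048)
def _ln_phi_pure_liquid(params: ParameterSet, cid: str, T: float, P: float) -> float:
    """ln phi of the pure (possibly subcooled) liquid reference state."""
    try:
        lnphi = ln_fugacity_coefficients(T, P, {cid: 1.0}, params, phase="liquid")
    except DensitySolveError as exc:
        raise ReferenceStateError(
            f"no pure-liquid root for {cid!r} at T={T} K, P={P} Pa: {exc}"
        ) from exc
    return lnphi[cid]


def activity_coefficient(
    solute: str,
    x_solute: float,
    T: float,
    params: ParameterSet,
    P: float = P_ATM,
    solvent: str = WATER,
) -> float:
    """Mole-fraction activity coefficient of ``solute`` in binary aqueous solution."""
    if not 0.0 <= x_solute <= 1.0:
        raise DomainError(f"x_solute must lie in [0, 1], got {x_solute}")
    ln0 = _ln_phi_pure_liquid(params, solute, T, P)
    if x_solute == 1.0:
        return 1.0
    lnphi = ln_fugacity_coefficients(
        T, P, {solute: x_solute, solvent: 1.0 - x_solute}, params, phase="liquid"
    )
    return float(np.exp(lnphi[solute] - ln0))


def water_activity_coefficient(
    solute: str,
    x_solute: float,
    T: float,
    params: ParameterSet,
    P: float = P_ATM,
    solvent: str = WATER,
) -> float:
    """Mole-fraction activity coefficient of water on the same pure-liquid scale."""
    if not 0.0 <= x_solute < 1.0:
        raise DomainError(f"x_solute must lie in [0, 1), got {x_solute}")
    ln0 = _ln_phi_pure_liquid(params, solvent, T, P)
    if x_solute == 0.0:
        return 1.0
    lnphi = ln_fugacity_coefficients(
        T, P, {solute: x_solute, solvent: 1.0 - x_solute}, params, phase="liquid"
    )
    return float(np.exp(lnphi[solvent] - ln0))


def osmotic_coefficient(
    solute: str,
    molality: float,
    T: float,
    params: ParameterSet,
    P: float = P_ATM,
) -> float:
    """Osmotic coefficient Phi at the given solute molality (mol/kg water)."""
    if molality <= 0:
        raise DomainError(f"molality must be positive, got {molality}")
    x_s = molality_to_mole_fraction(molality)
    gamma_w = water_activity_coefficient(solute, x_s, T, params, P=P)
    a_w = (1.0 - x_s) * gamma_w
    return float(-np.log(a_w) / (M_WATER * 1.0e-3 * molality))


# ---------------------------------------------------------------------------
# tabular observations (osmotic coefficients, solubilities)

DATATABLE_COLUMNS = ("T_K", "molality", "value", "sigma")


def read_data_table(source: str | Path) -> pd.DataFrame:
    """Read a (T_K, molality, value, sigma) observation table from CSV."""
    df = pd.read_csv(source)
    missing = [c for c in DATATABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"data table missing columns {missing}")
    return df[list(DATATABLE_COLUMNS)]


def write_data_table(df: pd.DataFrame, target: str | Path) -> None:
    df[list(DATATABLE_COLUMNS)].to_csv(target, index=False)
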