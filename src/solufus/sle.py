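"""Solid-liquid equilibrium: solubility prediction and the two fits.

For a pure solid in equilibrium with its saturated solution, neglecting the
solid/liquid heat-capacity difference, the saturation mole fraction obeys

    x_sat * gamma(x_sat, T) = exp[ -(dHfus/R) (1/T - 1/Tfus) ]

The right-hand side is the ideal solubility; gamma comes from the equation
of state.  Two inverse problems close the workflow: fitting the binary
interaction parameter kij to osmotic-coefficient data, and fitting dHfus to
a single measured solubility point when the calorimetric enthalpy is too
uncertain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq, minimize_scalar

from .components import ParameterSet
from .constants import P_ATM, R_GAS
from .errors import DomainError, FitError, SLEError
from .solution import (
    activity_coefficient,
    molality_to_mole_fraction,
    mole_fraction_to_molality,
    osmotic_coefficient,
)


@dataclass(frozen=True)
class MeltingProperties:
    """Melting temperature, fusion enthalpy and entropy with uncertainties.

    Units: ``T_fus`` K, ``dH_fus`` J/mol, ``dS_fus`` J/(K mol); each ``u_*``
    is the symmetric expanded uncertainty of the matching quantity.
    """

    substance: str
    T_fus: float
    dH_fus: float
    u_T_fus: float = 0.0
    u_dH_fus: float = 0.0

    def __post_init__(self) -> None:
        if self.T_fus <= 0 or self.dH_fus <= 0:
            raise DomainError("T_fus and dH_fus must be positive")

    @property
    def dS_fus(self) -> float:
        return self.dH_fus / self.T_fus

    @property
    def u_dS_fus(self) -> float:
        return self.dS_fus * math.hypot(
            self.u_dH_fus / self.dH_fus, self.u_T_fus / self.T_fus
        )


@dataclass
class FitResult:
    """Outcome of a one-parameter fit."""

    parameter: str
    value: float
    objective: float
    residuals: np.ndarray
    converged: bool
    n_iterations: int
    message: str = ""
    extra: dict = field(default_factory=dict)


def gamma_from_melting(x: float, T: float, melting: MeltingProperties) -> float:
    """Activity coefficient implied by a measured solubility and melting data.

    gamma = exp[-(dHfus/R)(1/T - 1/Tfus)] / x; at T = Tfus this reduces to
    the ideal-melt condition x*gamma = 1.
    """
    if not 0.0 < x < 1.0:
        raise DomainError(f"mole fraction must lie in (0, 1), got {x}")
    if T <= 0 or T > melting.T_fus:
        raise DomainError(f"T must lie in (0, T_fus], got {T}")
    return ideal_solubility(T, melting) / x


def ideal_solubility(T: float, melting: MeltingProperties) -> float:
    """Saturation mole fraction for an ideal solution (gamma = 1)."""
    if T <= 0:
        raise DomainError(f"T must be positive, got {T}")
    if T > melting.T_fus:
        raise DomainError(f"T={T} K exceeds T_fus={melting.T_fus} K; no solid phase")
    return math.exp(-(melting.dH_fus / R_GAS) * (1.0 / T - 1.0 / melting.T_fus))


@dataclass(frozen=True)
class SaturationPoint:
    """Converged saturation state of one solute at one temperature."""

    solute: str
    T: float
    x_sat: float
    molality: float
    gamma: float
    iterations: int
    residual: float


_SLE_DAMPING = 0.5
_SLE_TOL = 1.0e-10
_SLE_MAX_ITER = 200


def predict_solubility(
    T: float,
    melting: MeltingProperties,
    solute: str,
    params: ParameterSet,
    P: float = P_ATM,
    gamma_ideal: bool = False,
) -> SaturationPoint:
    """Solve the saturation condition x*gamma(x, T) = x_ideal(T).

    Damped fixed-point iteration x <- x_ideal/gamma(x) starting from the
    ideal solubility, followed by a bracketed root polish when the fixed
    point stalls.  ``gamma_ideal`` short-circuits gamma to 1 (ideal model).
    """
    x_ideal = ideal_solubility(T, melting)
    if gamma_ideal:
        return SaturationPoint(
            solute, T, x_ideal, mole_fraction_to_molality(x_ideal), 1.0, 0, 0.0
        )

    def gam(x: float) -> float:
        return activity_coefficient(solute, x, T, params, P=P)

    x = x_ideal
    n_iter = 0
    damping = 1.0  # full substitution steps; halved whenever the step grows
    prev_step = None
    for n_iter in range(1, _SLE_MAX_ITER + 1):
        g = gam(x)
        x_new = x_ideal / g
        if x_new >= 1.0:
            raise SLEError(
                f"saturation iteration left the physical range (x={x_new:.4g}) "
                f"for {solute} at T={T} K"
            )
        step = abs(x_new - x) / x_new
        if prev_step is not None and step > prev_step:
            damping = max(_SLE_DAMPING * damping, 0.1)
        prev_step = step
        x = (1.0 - damping) * x + damping * x_new
        if step < _SLE_TOL:
            break
    else:
        raise SLEError(
            f"saturation fixed point did not converge for {solute} at T={T} K "
            f"(last step {step:.3e})"
        )
    g = gam(x)
    residual = abs(x * g - x_ideal) / x_ideal
    if residual > 1.0e-8:
        # Newton/bisection polish on f(x) = x*gamma(x) - x_ideal
        f = lambda xx: xx * gam(xx) - x_ideal
        lo, hi = x * 0.9, min(x * 1.1, 0.999)
        try:
            x = brentq(f, lo, hi, xtol=1.0e-14, rtol=1.0e-12)
        except ValueError as exc:
            raise SLEError(f"saturation polish failed to bracket: {exc}") from exc
        g = gam(x)
        residual = abs(x * g - x_ideal) / x_ideal
    return SaturationPoint(
        solute, T, float(x), mole_fraction_to_molality(x), float(g), n_iter, float(residual)
    )


_HFUS_BAND = (5.0e3, 5.0e4)


def fit_hfus(
    target_molality: float,
    T: float,
    T_fus: float,
    solute: str,
    params: ParameterSet,
    P: float = P_ATM,
    band: tuple[float, float] = _HFUS_BAND,
) -> FitResult:
    """Fit dHfus so the predicted solubility matches one measured point.

    One-dimensional root solve in dHfus (J/mol) within the physically
    plausible band; the activity-coefficient model is untouched.  The
    activity coefficient at the target composition does not depend on dHfus,
    so the saturation condition can be inverted directly for a starting
    value; a secant iteration on the full prediction then removes any
    residual solver inconsistency.
    """
    if target_molality <= 0:
        raise DomainError(f"target molality must be positive, got {target_molality}")
    if T >= T_fus:
        raise DomainError(f"T={T} K must lie below T_fus={T_fus} K")
    x_target = molality_to_mole_fraction(target_molality)

    n_evals = 0

    def mismatch(dH: float) -> float:
        nonlocal n_evals
        n_evals += 1
        melting = MeltingProperties(solute, T_fus, dH)
        sat = predict_solubility(T, melting, solute, params, P=P)
        return (sat.molality - target_molality) / target_molality

    # closed-form inversion of x*gamma = exp[-(dH/R)(1/T - 1/Tfus)]
    gamma_t = activity_coefficient(solute, x_target, T, params, P=P)
    dH = -R_GAS * math.log(x_target * gamma_t) / (1.0 / T - 1.0 / T_fus)
    lo, hi = band
    if not lo <= dH <= hi:
        raise FitError(
            f"fitted dHfus {dH/1e3:.2f} kJ/mol falls outside the plausible band "
            f"[{lo/1e3:.1f}, {hi/1e3:.1f}] kJ/mol (gamma(x_target) = {gamma_t:.4g})"
        )
    resid = mismatch(dH)
    if abs(resid) > 1.0e-6:
        # secant refinement of the one-dimensional root
        a, fa = dH, resid
        b, fb = dH * 1.001, mismatch(dH * 1.001)
        for _ in range(20):
            if abs(fb) <= 1.0e-8 or fb == fa:
                break
            c = min(max(b - fb * (b - a) / (fb - fa), lo), hi)
            a, fa = b, fb
            b, fb = c, mismatch(c)
        dH, resid = b, fb
        if abs(resid) > 1.0e-6:
            raise FitError(f"dHfus refinement stalled at residual {resid:.3e}")
    return FitResult(
        parameter="dH_fus",
        value=float(dH),
        objective=abs(resid),
        residuals=np.array([resid]),
        converged=abs(resid) <= 1.0e-6,
        n_iterations=n_evals,
        message=f"dH_fus = {dH/1e3:.4g} kJ/mol, relative residual {resid:.2e}",
    )


def fit_kij(
    data: pd.DataFrame,
    pair: tuple[str, str],
    params: ParameterSet,
    P: float = P_ATM,
    bounds: tuple[float, float] = (-0.3, 0.3),
) -> FitResult:
    """Least-squares fit of the reference kij to osmotic-coefficient data.

    ``data`` is a (T_K, molality, value, sigma) table of osmotic
    coefficients.  Only the 298.15 K intercept is optimized; any declared
    temperature slope of the pair is held fixed.
    """
    if len(data) < 3:
        raise FitError(f"need at least 3 osmotic data points, got {len(data)}")
    solute = next(c for c in pair if c != "water")

    n_evals = 0

    def residuals(kref: float) -> np.ndarray:
        p = params.with_kij(pair[0], pair[1], kref)
        model = np.array(
            [
                osmotic_coefficient(solute, row.molality, row.T_K, p, P=P)
                for row in data.itertuples()
            ]
        )
        return model - data["value"].to_numpy()

    def objective(kref: float) -> float:
        nonlocal n_evals
        n_evals += 1
        return float(np.sum(residuals(kref) ** 2))

    res = minimize_scalar(objective, bounds=bounds, method="bounded",
                          options={"xatol": 1.0e-6})
    if not res.success:
        raise FitError(f"kij optimization failed: {res.message}")
    resid = residuals(res.x)
    start = params.binary(*pair).kij_ref if any(
        b.pair == tuple(sorted(pair)) for b in params.binaries
    ) else 0.0
    return FitResult(
        parameter="kij_ref",
        value=float(res.x),
        objective=float(res.fun),
        residuals=resid,
        converged=bool(res.success),
        n_iterations=n_evals,
        message=f"kij_ref = {res.x:.5f}, SSE = {res.fun:.3e}",
        extra={"initial_kij_ref": start},
    )


def ard(model: np.ndarray, exp: np.ndarray) -> float:
    """Average absolute relative deviation in percent: 100/N sum|1 - m/e|."""
    model = np.asarray(model, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if model.shape != exp.shape:
        raise DomainError(f"series lengths differ: {model.shape} vs {exp.shape}")
    if model.size == 0:
        raise DomainError("empty series")
    if np.any(exp == 0):
        raise DomainError("experimental values must be nonzero")
    return float(100.0 / model.size * np.sum(np.abs(1.0 - model / exp)))


# ---------------------------------------------------------------------------
# solubility-curve I/O and shipped melting-property fixture

CURVE_COLUMNS = ("T_K", "molality_pred", "x_pred", "gamma_solute")


def solubility_curve(
    temperatures: np.ndarray,
    melting: MeltingProperties,
    solute: str,
    params: ParameterSet,
    P: float = P_ATM,
    gamma_ideal: bool = False,
) -> pd.DataFrame:
    """Predicted saturation curve over a temperature grid as a data frame."""
    rows = []
    for T in np.asarray(temperatures, dtype=float):
        sat = predict_solubility(T, melting, solute, params, P=P, gamma_ideal=gamma_ideal)
        rows.append((T, sat.molality, sat.x_sat, sat.gamma))
    return pd.DataFrame(rows, columns=list(CURVE_COLUMNS))


def load_default_melting() -> dict[str, MeltingProperties]:
    """The shipped calorimetric melting properties for glycine and l-alanine."""
    path = Path(resources.files("solufus.data") / "melting.yaml")
    doc = yaml.safe_load(path.read_text())
    out = {}
    for entry in doc["melting_properties"]:
        out[entry["substance"]] = MeltingProperties(
            substance=entry["substance"],
            T_fus=float(entry["T_fus_K"]),
            dH_fus=float(entry["dH_fus_J_per_mol"]),
            u_T_fus=float(entry.get("u_T_fus_K", 0.0)),
            u_dH_fus=float(entry.get("u_dH_fus_J_per_mol", 0.0)),
        )
    return out
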