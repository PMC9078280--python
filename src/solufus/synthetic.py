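"""Seeded generators for every input the pipeline consumes.

The thermogram generator emulates the phenomenology of chip-calorimeter
melting scans that the reduction stage relies on — and nothing more:

* an apparent onset that shifts linearly with heating rate (thermal lag /
  superheating), ``T_on(beta) = T_fus + lag_slope * beta``;
* a melting peak whose baseline-subtracted area equals sample mass times
  the specific fusion enthalpy, independent of peak shape;
* a mildly sloped instrument baseline and additive Gaussian noise.

Peak shapes are a Gaussian leading edge with either an exponential or a
Gaussian trailing tail; the reduction must not depend on the shape, so both
are available.  For the Gaussian leading edge the tangent-at-inflection
onset construction lands exactly two edge widths below the apex, which the
generator uses to plant the apparent onset analytically.

All generators are pure functions of their seed and settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import ParameterSet
from .constants import P_ATM
from .errors import DomainError
from .fsc import Thermogram
from .sle import MeltingProperties, predict_solubility
from .solution import DATATABLE_COLUMNS, osmotic_coefficient


@dataclass(frozen=True)
class ScanProtocol:
    """Design of a synthetic melting-scan campaign.

    Defaults mirror a realistic chip-calorimetry study of a small organic
    crystal: rates spanning 1000-10000 K/s, sub-100-ng samples, an onset
    lag of a few kelvin across the rate range, and per-scan onset scatter
    of a few kelvin.
    """

    rates: tuple[float, ...] = (1000.0, 2000.0, 4000.0, 6000.0, 8000.0, 10000.0)
    scans_per_rate: int = 8
    mass_range_g: tuple[float, float] = (20.0e-9, 90.0e-9)
    T_fus: float = 608.0
    specific_enthalpy_J_per_g: float = 250.0
    lag_slope_K_per_rate: float = 4.0e-4  # 4 K shift across 10^4 K/s
    onset_scatter_K: float = 3.0
    noise_rel: float = 0.01
    seed: int = 0
    edge_width_K: float = 3.0
    tail_width_K: float = 2.0
    tail_shape: str = "exponential"  # or "gaussian"
    baseline_slope_rel: float = 0.002  # baseline tilt per K, relative to peak height
    T_start: float = 450.0
    dT_step: float = 0.2

    def __post_init__(self) -> None:
        if min(self.rates) <= 0 or self.scans_per_rate <= 0:
            raise DomainError("rates and scans_per_rate must be positive")
        if self.T_fus <= 0 or self.specific_enthalpy_J_per_g <= 0:
            raise DomainError("planted melting properties must be positive")
        if self.mass_range_g[0] <= 0 or self.mass_range_g[1] < self.mass_range_g[0]:
            raise DomainError("invalid mass range")
        if self.tail_shape not in ("exponential", "gaussian"):
            raise DomainError(f"unknown tail shape {self.tail_shape!r}")


def _peak_profile(T: np.ndarray, apex: float, height: float, s: float, tau: float, shape: str) -> np.ndarray:
    lead = height * np.exp(-0.5 * ((T - apex) / s) ** 2)
    if shape == "exponential":
        tail = height * np.exp(-(T - apex) / tau)
    else:
        tail = height * np.exp(-0.5 * ((T - apex) / tau) ** 2)
    return np.where(T <= apex, lead, tail)


def _peak_area_T(height: float, s: float, tau: float, shape: str) -> float:
    """Analytic area of the piecewise profile in temperature units."""
    lead = height * s * math.sqrt(math.pi / 2.0)
    if shape == "exponential":
        tail = height * tau
    else:
        tail = height * tau * math.sqrt(math.pi / 2.0)
    return lead + tail


def simulate_thermogram(
    scan_id: str,
    beta: float,
    mass_g: float,
    protocol: ScanProtocol,
    rng: np.random.Generator,
) -> Thermogram:
    """One synthetic heating scan with a planted apparent onset and area."""
    p = protocol
    onset = p.T_fus + p.lag_slope_K_per_rate * beta + (
        rng.normal(0.0, p.onset_scatter_K) if p.onset_scatter_K > 0 else 0.0
    )
    # the tangent construction on a Gaussian edge intersects the baseline
    # exactly two edge widths below the apex
    apex = onset + 2.0 * p.edge_width_K
    T_max = apex + max(8.0 * p.tail_width_K, 25.0) + 15.0
    T = np.arange(p.T_start, T_max, p.dT_step)
    time = (T - T[0]) / beta
    area_T = beta * mass_g * p.specific_enthalpy_J_per_g  # integral over T of (W dT)
    height = area_T / _peak_area_T(1.0, p.edge_width_K, p.tail_width_K, p.tail_shape)
    signal = _peak_profile(T, apex, height, p.edge_width_K, p.tail_width_K, p.tail_shape)
    baseline = 0.05 * height + p.baseline_slope_rel * height * (T - T[0])
    noise = rng.normal(0.0, p.noise_rel * height, size=T.shape) if p.noise_rel > 0 else 0.0
    return Thermogram(
        scan_id=scan_id,
        beta=beta,
        time_s=time,
        T_K=T,
        heatflow_W=signal + baseline + noise,
        metadata={
            "sample_mass_g": mass_g,
            "stage": "melt",
            "T_max_K": float(T[-1]),
            "oil_coated": "true",
        },
    )


def simulate_thermogram_set(protocol: ScanProtocol) -> list[Thermogram]:
    """A full synthetic scan campaign; deterministic for a given seed."""
    rng = np.random.default_rng(protocol.seed)
    out = []
    k = 0
    for beta in protocol.rates:
        for _ in range(protocol.scans_per_rate):
            mass = rng.uniform(*protocol.mass_range_g)
            out.append(simulate_thermogram(f"scan{k:03d}_b{int(beta)}", beta, mass, protocol, rng))
            k += 1
    return out


def simulate_mass_curves(
    mass_g: float,
    cp_reference,
    T_window: tuple[float, float] = (320.0, 440.0),
    noise_rel: float = 0.0,
    seed: int = 0,
    n_points: int = 120,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched heating/cooling heat-capacity curves with a planted mass.

    Returns two (n, 2) arrays of (T in K, Cp in J/K) suitable for
    :func:`solufus.fsc.determine_sample_mass`.
    """
    rng = np.random.default_rng(seed)
    T = np.linspace(*T_window, n_points)
    cp = np.asarray(cp_reference(T), dtype=float)
    heating = np.column_stack([T, mass_g * cp * (1.0 + rng.normal(0, noise_rel, T.shape))])
    cooling = np.column_stack([T, mass_g * cp * (1.0 + rng.normal(0, noise_rel, T.shape))])
    return heating, cooling


def simulate_osmotic_table(
    solute: str,
    params: ParameterSet,
    planted_kij: float,
    molalities,
    T: float = 298.15,
    noise_rel: float = 0.0,
    seed: int = 0,
    P: float = P_ATM,
) -> pd.DataFrame:
    """Osmotic-coefficient observations from the forward model with a planted kij."""
    rng = np.random.default_rng(seed)
    p = params.with_kij(solute, "water", planted_kij)
    rows = []
    for m in molalities:
        phi = osmotic_coefficient(solute, float(m), T, p, P=P)
        obs = phi * (1.0 + (rng.normal(0.0, noise_rel) if noise_rel > 0 else 0.0))
        rows.append((T, float(m), obs, noise_rel * phi))
    return pd.DataFrame(rows, columns=list(DATATABLE_COLUMNS))


def simulate_solubility_table(
    solute: str,
    params: ParameterSet,
    melting: MeltingProperties,
    temperatures,
    noise_rel: float = 0.0,
    seed: int = 0,
    P: float = P_ATM,
) -> pd.DataFrame:
    """Saturation molalities from the forward model with multiplicative noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for T in temperatures:
        T = float(T)
        if T >= melting.T_fus:
            raise DomainError(f"T={T} K is not below T_fus={melting.T_fus} K")
        sat = predict_solubility(T, melting, solute, params, P=P)
        obs = sat.molality * (1.0 + (rng.normal(0.0, noise_rel) if noise_rel > 0 else 0.0))
        rows.append((T, obs, obs, noise_rel * sat.molality))
    df = pd.DataFrame(rows, columns=list(DATATABLE_COLUMNS))
    return df
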