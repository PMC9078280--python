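"""Fast-scanning-calorimetry (FSC) data reduction.

A chip calorimeter heats a sub-100-ng sample at rates of 10^3-10^4 K/s, fast
enough to melt thermally labile solids (amino acids) before they decompose.
Each heating scan yields a heat-flow-rate curve with an endothermic melting
peak.  The reduction chain implemented here:

1. sample mass from the solid heat-capacity plateau, m0 = Cp/cp_ref;
2. per-scan peak onset (baseline/leading-edge-tangent construction) and
   peak area (baseline-subtracted integral over time, in joules);
3. melting temperature as the zero-heating-rate intercept of onset vs rate,
   which absorbs thermal lag and superheating;
4. molar fusion enthalpy from the through-origin slope of peak area vs
   sample mass, times the molar mass;
5. fusion entropy dS = dH/Tfus with first-order uncertainty propagation.

The onset construction: intersect the extrapolated pre-peak baseline with
the tangent to the leading edge at its inflection point.  Onsets measured at
finite rate are apparent (lag- and superheating-shifted); only the
extrapolated intercept is a thermodynamic melting temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import t as student_t

from .errors import (
    AmbiguousPeakError,
    DomainError,
    IllConditionedFitError,
    InsufficientDataError,
    MassLossError,
    NoPeakError,
)

MASS_UNCERTAINTY_REL = 0.11
"""Relative uncertainty of the chip-sensor sample-mass determination."""


@dataclass(frozen=True)
class UncertainValue:
    """A scalar with a symmetric expanded uncertainty."""

    value: float
    uncertainty: float

    def covers(self, truth: float) -> bool:
        return abs(self.value - truth) <= self.uncertainty

    def __format__(self, spec: str) -> str:
        return f"{self.value:{spec}} +/- {self.uncertainty:{spec}}"


@dataclass(frozen=True, eq=False)
class Thermogram:
    """One FSC heating scan: heating rate plus (time, T, heat-flow-rate) series.

    Heat flow is signed endotherm-positive (melting peaks point up) in watts.
    """

    scan_id: str
    beta: float  # heating rate, K/s
    time_s: np.ndarray
    T_K: np.ndarray
    heatflow_W: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise DomainError(f"heating rate must be positive, got {self.beta}")
        T = np.asarray(self.T_K, dtype=float)
        if len(T) != len(self.time_s) or len(T) != len(self.heatflow_W):
            raise DomainError("time, temperature and heat-flow series must align")
        if np.any(np.diff(T) <= 0):
            raise DomainError("temperature must be strictly increasing on a heating scan")


@dataclass(frozen=True)
class PeakMeasurement:
    """Reduced quantities of one scan's melting peak."""

    scan_id: str
    beta: float  # K/s
    T_onset: float  # K
    dH: float  # peak area, J
    mass: float | None = None  # sample mass, g

    def __post_init__(self) -> None:
        if self.dH <= 0:
            raise DomainError("melting peak area must be positive")


# ---------------------------------------------------------------------------
# stage (i): sample mass


def determine_sample_mass(
    heating: np.ndarray,
    cooling: np.ndarray,
    cp_reference: Callable[[np.ndarray], np.ndarray],
    window: tuple[float, float] | None = None,
    mismatch_tol: float = 0.10,
    mass_uncertainty_rel: float = MASS_UNCERTAINTY_REL,
) -> UncertainValue:
    """Sample mass in grams from matched heating/cooling Cp curves.

    ``heating`` and ``cooling`` are (n, 2) arrays of (T in K, Cp in J/K);
    ``cp_reference`` maps T to the specific heat capacity in J/(g K).
    Heating/cooling disagreement beyond ``mismatch_tol`` signals mass loss
    (evaporation of volatiles between the two scans) and raises.
    """
    heating = np.asarray(heating, dtype=float)
    cooling = np.asarray(cooling, dtype=float)
    lo = max(heating[:, 0].min(), cooling[:, 0].min())
    hi = min(heating[:, 0].max(), cooling[:, 0].max())
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi <= lo:
        raise DomainError("heating and cooling curves share no evaluation window")
    grid = np.linspace(lo, hi, 201)
    ch = np.interp(grid, heating[:, 0], heating[:, 1])
    cc = np.interp(grid, cooling[:, 0], cooling[:, 1])
    mean_cp = 0.5 * (ch + cc)
    scale = np.mean(np.abs(mean_cp))
    mismatch = np.max(np.abs(ch - cc)) / scale
    if mismatch > mismatch_tol:
        raise MassLossError(
            f"heating/cooling Cp curves disagree by {100*mismatch:.1f}% "
            f"(> {100*mismatch_tol:.0f}%): mass loss suspected"
        )
    cp = np.asarray(cp_reference(grid), dtype=float)
    if np.any(cp <= 0):
        raise DomainError("reference specific heat capacity must be positive on the window")
    m0 = float(np.mean(mean_cp / cp))
    return UncertainValue(m0, mass_uncertainty_rel * m0)


def cp_table_reference(table: pd.DataFrame, substance: str) -> Callable[[np.ndarray], np.ndarray]:
    """Interpolating cp(T) in J/(g K) from a (substance, T_K, cp_J_per_gK) table."""
    rows = table[table["substance"] == substance]
    if rows.empty:
        raise DomainError(f"no cp reference data for substance {substance!r}")
    Tv = rows["T_K"].to_numpy(dtype=float)
    cv = rows["cp_J_per_gK"].to_numpy(dtype=float)
    order = np.argsort(Tv)
    return lambda T: np.interp(T, Tv[order], cv[order])


# ---------------------------------------------------------------------------
# stage (ii): peak onset and area


def detect_melting_peak(
    tg: Thermogram,
    baseline_window: float = 20.0,
    baseline_gap: float = 5.0,
    noise_sigmas: float = 6.0,
) -> PeakMeasurement:
    """Onset and area of the dominant endothermic peak of one scan.

    Baseline: one straight line fitted jointly to a pre-peak and a post-peak
    window (each ``baseline_window`` K wide, separated from the peak region
    by ``baseline_gap`` K).  Onset: intersection of that baseline with the
    tangent at the leading edge's inflection point.  Area: integral of the
    baseline-subtracted heat-flow rate over time, in joules.
    """
    T = np.asarray(tg.T_K, dtype=float)
    hf = np.asarray(tg.heatflow_W, dtype=float)
    t = np.asarray(tg.time_s, dtype=float)
    n = len(T)
    if n < 50:
        raise DomainError("thermogram too short for peak analysis")

    win = min(31, (n // 20) * 2 + 1)
    win = max(win, 5)
    sm = savgol_filter(hf, win, 3)
    noise = float(np.std(hf - sm))

    # coarse detrend through the end segments, for peak finding only
    edge = max(n // 10, 5)
    idx_edge = np.r_[0:edge, n - edge : n]
    coef = np.polyfit(T[idx_edge], sm[idx_edge], 1)
    sig0 = sm - np.polyval(coef, T)
    span = float(np.ptp(sig0))
    if span <= 0.0:
        raise NoPeakError("flat signal: no melting peak present")
    prom_min = noise_sigmas * noise + 1.0e-3 * span
    peaks, props = find_peaks(sig0, prominence=prom_min)
    if len(peaks) == 0:
        raise NoPeakError(
            f"no peak with prominence above {prom_min:.3g} W "
            f"(noise {noise:.3g} W) found"
        )
    prom = props["prominences"]
    order = np.argsort(prom)[::-1]
    comparable = [peaks[k] for k in order if prom[k] >= 0.5 * prom[order[0]]]
    if len(comparable) > 1:
        raise AmbiguousPeakError([float(T[k]) for k in comparable])
    ipk = int(comparable[0])
    height = sig0[ipk]

    # peak region: walk out to where the detrended signal falls below a floor
    floor = max(0.005 * height, 2.0 * noise)
    il = ipk
    while il > 0 and sig0[il] > floor:
        il -= 1
    ir = ipk
    while ir < n - 1 and sig0[ir] > floor:
        ir += 1

    # joint linear baseline through pre- and post-peak windows
    pre = (T >= T[il] - baseline_gap - baseline_window) & (T <= T[il] - baseline_gap)
    post = (T >= T[ir] + baseline_gap) & (T <= T[ir] + baseline_gap + baseline_window)
    base_mask = pre | post
    if base_mask.sum() < 4 or pre.sum() < 2 or post.sum() < 2:
        raise DomainError(
            "not enough points outside the peak for baseline fitting; "
            "widen the scan range or shrink the baseline windows"
        )
    bcoef = np.polyfit(T[base_mask], hf[base_mask], 1)
    y = hf - np.polyval(bcoef, T)
    ysm = sm - np.polyval(bcoef, T)

    # extend integration bounds to the baseline crossings
    il2 = il
    while il2 > 0 and ysm[il2] > 0.0:
        il2 -= 1
    ir2 = ir
    while ir2 < n - 1 and ysm[ir2] > 0.0:
        ir2 += 1
    area = float(np.trapezoid(y[il2 : ir2 + 1], t[il2 : ir2 + 1]))
    if area <= 0:
        raise NoPeakError("baseline-subtracted peak area is not positive")

    # leading-edge tangent at the inflection point.  The derivative is
    # smoothed with a positive (moving-average) kernel over roughly 1 K:
    # unlike a polynomial filter it cannot overshoot at sharp corners, and
    # at an inflection point its value bias vanishes to second order.
    step = float(np.mean(np.diff(T)))
    size_d = max(3, int(round(1.0 / step)) | 1)
    grad = uniform_filter1d(np.gradient(y, T), size=size_d, mode="nearest")
    y_avg = uniform_filter1d(y, size=size_d, mode="nearest")
    lead = slice(il2, ipk + 1)
    i_inf = il2 + int(np.argmax(grad[lead]))
    slope = grad[i_inf]
    if slope <= 0:
        raise NoPeakError("no rising leading edge found")
    T_onset = float(T[i_inf] - y_avg[i_inf] / slope)
    if T_onset >= T[ipk]:
        raise NoPeakError("onset construction landed above the peak maximum")

    return PeakMeasurement(
        scan_id=tg.scan_id,
        beta=tg.beta,
        T_onset=T_onset,
        dH=area,
        mass=tg.metadata.get("sample_mass_g"),
    )


# ---------------------------------------------------------------------------
# stage (ii) aggregation: zero-rate extrapolation and mass regression


@dataclass(frozen=True)
class ZeroRateFit:
    """Zero-heating-rate extrapolation of apparent onsets."""

    T_fus: UncertainValue
    slope: float  # K per (K/s): thermal-lag proxy
    se_intercept: float
    t_factor: float
    n: int


def extrapolate_zero_rate(
    measurements: Sequence[PeakMeasurement],
    calibration_u: float = 0.0,
) -> ZeroRateFit:
    """Melting temperature as the onset-vs-rate intercept at beta -> 0.

    Ordinary least squares of T_onset against beta; the reported uncertainty
    is the 95% Student-t expanded intercept standard error combined in
    quadrature with the temperature-calibration uncertainty.
    """
    if len({round(m.beta, 9) for m in measurements}) < 3:
        raise InsufficientDataError("need onsets at >= 3 distinct heating rates")
    beta = np.array([m.beta for m in measurements], dtype=float)
    Ton = np.array([m.T_onset for m in measurements], dtype=float)
    n = len(beta)
    X = np.column_stack([np.ones(n), beta])
    coef, res_ss, *_ = np.linalg.lstsq(X, Ton, rcond=None)
    fitted = X @ coef
    dof = n - 2
    s2 = float(np.sum((Ton - fitted) ** 2)) / dof if dof > 0 else 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se_int = math.sqrt(cov[0, 0])
    tf = float(student_t.ppf(0.975, dof)) if dof > 0 else float("nan")
    u = math.hypot(tf * se_int, calibration_u) if dof > 0 else calibration_u
    return ZeroRateFit(
        T_fus=UncertainValue(float(coef[0]), u),
        slope=float(coef[1]),
        se_intercept=se_int,
        t_factor=tf,
        n=n,
    )


@dataclass(frozen=True)
class EnthalpyFit:
    """Mass-proportional peak-area regression reduced to a molar enthalpy."""

    dH_molar: UncertainValue  # J/mol
    specific: float  # J/g
    se_specific: float
    n: int


def molar_fusion_enthalpy(
    measurements: Sequence[PeakMeasurement],
    molar_mass: float,
    mass_uncertainty_rel: float = MASS_UNCERTAINTY_REL,
) -> EnthalpyFit:
    """Molar fusion enthalpy from the through-origin slope of dH vs mass.

    The peak area grows linearly with sample mass regardless of heating
    rate; the through-origin slope is the specific fusion enthalpy in J/g.
    The reported uncertainty combines the slope standard error with the
    relative sample-mass uncertainty in quadrature.
    """
    if molar_mass <= 0:
        raise DomainError("molar mass must be positive")
    ms = [m for m in measurements if m.mass is not None]
    if len(ms) < 3:
        raise InsufficientDataError("need >= 3 peak measurements with known masses")
    mass = np.array([m.mass for m in ms], dtype=float)
    dH = np.array([m.dH for m in ms], dtype=float)
    if np.ptp(mass) < 1.0e-12 * np.mean(mass):
        raise IllConditionedFitError("all sample masses are equal; slope is unidentifiable")
    sxx = float(np.sum(mass**2))
    slope = float(np.sum(mass * dH)) / sxx
    dof = len(ms) - 1
    s2 = float(np.sum((dH - slope * mass) ** 2)) / dof
    se_slope = math.sqrt(s2 / sxx)
    u_rel = math.hypot(se_slope / slope, mass_uncertainty_rel)
    molar = slope * molar_mass
    return EnthalpyFit(
        dH_molar=UncertainValue(molar, abs(molar) * u_rel),
        specific=slope,
        se_specific=se_slope,
        n=len(ms),
    )


def fusion_entropy(dH_fus: UncertainValue | float, T_fus: UncertainValue | float) -> UncertainValue:
    """dS = dH/Tfus in J/(K mol), with first-order uncertainty propagation."""
    hv, hu = (dH_fus.value, dH_fus.uncertainty) if isinstance(dH_fus, UncertainValue) else (float(dH_fus), 0.0)
    tv, tu = (T_fus.value, T_fus.uncertainty) if isinstance(T_fus, UncertainValue) else (float(T_fus), 0.0)
    if hv < 0 or tv <= 0:
        raise DomainError("dH_fus must be nonnegative and T_fus positive")
    value = hv / tv
    if hv == 0.0:
        return UncertainValue(0.0, hu / tv)
    u = value * math.hypot(hu / hv, tu / tv)
    return UncertainValue(value, u)


# ---------------------------------------------------------------------------
# full scan-set reduction


@dataclass(frozen=True, eq=False)
class ReductionSummary:
    """Melting properties reduced from one scan set."""

    substance: str
    T_fus: UncertainValue
    dH_fus: UncertainValue  # J/mol
    dS_fus: UncertainValue  # J/(K mol)
    per_scan: pd.DataFrame


def reduce_scan_set(
    thermograms: Sequence[Thermogram],
    molar_mass: float,
    substance: str = "",
    calibration_u: float = 0.0,
    **peak_kwargs,
) -> ReductionSummary:
    """Run peak detection, zero-rate extrapolation and the mass regression."""
    measurements = [detect_melting_peak(tg, **peak_kwargs) for tg in thermograms]
    zr = extrapolate_zero_rate(measurements, calibration_u=calibration_u)
    ef = molar_fusion_enthalpy(measurements, molar_mass)
    ds = fusion_entropy(ef.dH_molar, zr.T_fus)
    per_scan = pd.DataFrame(
        [
            (m.scan_id, m.beta, m.T_onset, m.dH, m.mass)
            for m in measurements
        ],
        columns=["scan_id", "beta", "T_onset", "dH_area", "mass"],
    )
    return ReductionSummary(substance, zr.T_fus, ef.dH_molar, ds, per_scan)


# ---------------------------------------------------------------------------
# thermogram CSV dialect

_META_PREFIX = "# "


def write_thermogram(tg: Thermogram, target: str | Path) -> None:
    """Write the '# key=value' header + time_s,T_K,heatflow_W CSV dialect."""
    lines = [f"{_META_PREFIX}scan_id={tg.scan_id}", f"{_META_PREFIX}rate_K_per_s={tg.beta!r}"]
    for k, v in tg.metadata.items():
        v_txt = repr(float(v)) if isinstance(v, (float, np.floating)) else v
        lines.append(f"{_META_PREFIX}{k}={v_txt}")
    lines.append("time_s,T_K,heatflow_W")
    for ti, Ti, hi in zip(tg.time_s, tg.T_K, tg.heatflow_W):
        lines.append(f"{float(ti)!r},{float(Ti)!r},{float(hi)!r}")
    Path(target).write_text("\n".join(lines) + "\n")


def read_thermogram(source: str | Path) -> Thermogram:
    """Read one scan written by :func:`write_thermogram`."""
    meta: dict = {}
    rows = []
    header_seen = False
    for line in Path(source).read_text().splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
        elif not header_seen:
            header_seen = True  # column header
        elif line.strip():
            rows.append([float(v) for v in line.split(",")])
    if "scan_id" not in meta or "rate_K_per_s" not in meta:
        raise DomainError("thermogram file missing scan_id/rate_K_per_s header")
    arr = np.asarray(rows, dtype=float)
    scan_id = meta.pop("scan_id")
    beta = float(meta.pop("rate_K_per_s"))
    for k in list(meta):
        try:
            meta[k] = float(meta[k])
        except ValueError:
            pass
    return Thermogram(
        scan_id=scan_id,
        beta=beta,
        time_s=arr[:, 0],
        T_K=arr[:, 1],
        heatflow_W=arr[:, 2],
        metadata=meta,
    )


def load_synthetic_cp_table() -> pd.DataFrame:
    """The shipped solid heat-capacity table (synthetic stand-in).

    The reduction needs a literature cp(T) of the crystalline solid; the
    shipped table carries plausible magnitudes (~1.3-1.9 J/(g K) between
    300 and 480 K) so the mass-determination stage is exercisable end to
    end.  Replace it with measured values for quantitative work.
    """
    from importlib import resources

    return pd.read_csv(Path(resources.files("solufus.data") / "cp_solid_synthetic.csv"))
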