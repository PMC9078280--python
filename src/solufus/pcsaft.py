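"""PC-SAFT equation of state for associating mixtures.

The residual Helmholtz energy is the sum of hard-chain, dispersion and
association contributions,

    a_res = a_hc + a_disp + a_assoc        (reduced, per mole of molecules)

with the hard-sphere mixture described by the Boublik-Mansoori moments, the
dispersion term by the two universal power series in packing fraction, and
association by a Wertheim-type site balance.  All components handled here are
either non-associating or carry the 2B scheme (one proton-donor site A and
one proton-acceptor site B; only A-B bonds form).  Cross parameters use the
Berthelot-Lorentz combining rules

    u_ij  = sqrt(u_i u_j) (1 - k_ij),      sigma_ij = (sigma_i + sigma_j)/2

and cross association uses the arithmetic-mean energy with the
sigma-ratio-scaled geometric-mean volume (Wolbach-Sandler form).

Derivatives
-----------
The compressibility factor and the residual chemical potentials are exact
derivatives of the residual Helmholtz function, evaluated by complex-step
differentiation: the Helmholtz routine is written to accept complex density
and mole numbers, so ``Im f(z + ih)/h`` yields machine-precision derivatives
with no subtractive cancellation.  Real central finite differences serve as
an independent cross-check in the test suite.

Internally everything is SI (metres, molecules/m^3); parameters enter in the
literature units and are converted once.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .components import ParameterSet
from .constants import ANGSTROM, ETA_MAX, KB
from .errors import (
    ConvergenceError,
    DensitySolveError,
    DomainError,
    PackingFractionError,
)

# Universal dispersion-series constants of the perturbed-chain model
# (model constants, independent of any substance).
_A = np.array(
    [
        [0.9105631445, -0.3084016918, -0.0906148351],
        [0.6361281449, 0.1860531159, 0.4527842806],
        [2.6861347891, -2.5030047259, 0.5962700728],
        [-26.547362491, 21.419793629, -1.7241829131],
        [97.759208784, -65.255885330, -4.1302112531],
        [-159.59154087, 83.318680481, 13.776631870],
        [91.297774084, -33.746922930, -8.6728470368],
    ]
)
_B = np.array(
    [
        [0.7240946941, -0.5755498075, 0.0976883116],
        [2.2382791861, 0.6995095521, -0.2557574982],
        [-4.0025849485, 3.8925673390, -9.1558561530],
        [-21.003576815, -17.215471648, 20.642075974],
        [26.855641363, 192.67226447, -38.804430052],
        [206.55133841, -161.82646165, 93.626774077],
        [-355.60235612, -165.20769346, -29.666905585],
    ]
)

_ASSOC_TOL = 1.0e-12
_ASSOC_SSI_TOL = 1.0e-6
_ASSOC_MAX_ITER = 500
_ASSOC_SSI_ITER = 60
_ASSOC_DAMPING = 0.5
_COMPLEX_STEP = 1.0e-150


@dataclass(frozen=True)
class MixtureState:
    """Temperature, pressure, composition and (solved) density of one phase.

    ``x`` is stored aligned with ``ids``; ``rho`` is the total molecular
    number density in 1/m^3 (``None`` before a density solution), ``eta`` the
    corresponding packing fraction.
    """

    T: float
    ids: tuple[str, ...]
    x: tuple[float, ...]
    P: float | None = None
    rho: float | None = None
    eta: float | None = None
    phase: str | None = None
    stable: bool | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise DomainError(f"temperature must be positive, got {self.T}")
        xa = np.asarray(self.x, dtype=float)
        if np.any(xa < 0):
            raise DomainError("mole fractions must be nonnegative")
        if abs(xa.sum() - 1.0) > 1.0e-12:
            raise DomainError(f"mole fractions must sum to 1, got {xa.sum()!r}")
        if len(self.ids) != len(self.x):
            raise DomainError("ids and x must have equal length")

    def x_of(self, cid: str) -> float:
        return self.x[self.ids.index(cid)]


@dataclass(frozen=True)
class HelmholtzParts:
    """Reduced residual Helmholtz energy a_res/RT split into named parts."""

    hc: float
    disp: float
    assoc: float

    @property
    def total(self) -> float:
        return self.hc + self.disp + self.assoc


@dataclass(frozen=True)
class AssociationSolution:
    """Unbonded site fractions X and association strengths Delta (m^3).

    ``X`` maps component id to ``{"A": X_A, "B": X_B}``; non-associating
    components carry both fractions equal to 1.  ``delta`` is the full
    donor-acceptor strength matrix aligned with ``ids``.
    """

    ids: tuple[str, ...]
    X: Mapping[str, Mapping[str, float]]
    delta: np.ndarray


# ---------------------------------------------------------------------------
# temperature-dependent parameter tables


@lru_cache(maxsize=512)
def _tstate(params: ParameterSet, ids: tuple[str, ...], T: float):
    """Arrays of T-evaluated parameters for the ordered component subset."""
    comps = [params[c] for c in ids]
    m = np.array([c.m_seg for c in comps])
    sig = np.array([c.sigma(T) for c in comps]) * ANGSTROM
    u = np.array([c.u_k for c in comps])
    eps = np.array([c.eps_assoc_k for c in comps])
    kap = np.array([c.kappa_assoc for c in comps])
    n = len(ids)
    kij = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            kij[i, j] = kij[j, i] = params.kij(ids[i], ids[j], T, missing_as_zero=True)
    d = sig * (1.0 - 0.12 * np.exp(-3.0 * u / T))
    sij = 0.5 * (sig[:, None] + sig[None, :])
    uij = np.sqrt(np.outer(u, u)) * (1.0 - kij)
    # cross association: arithmetic-mean energy, sigma-scaled geometric volume
    epsij = 0.5 * (eps[:, None] + eps[None, :])
    kapij = np.sqrt(np.outer(kap, kap)) * (np.sqrt(np.outer(sig, sig)) / sij) ** 3
    return m, sig, u, d, sij, uij, epsij, kapij, kap


def _zeta(rho, x, m, d):
    return [np.pi / 6.0 * rho * np.sum(x * m * d**k) for k in range(4)]


def _check_eta(eta) -> None:
    e = eta.real if np.iscomplexobj(eta) else eta
    if e >= ETA_MAX:
        raise PackingFractionError(float(e))


def _g_contact(d, z2, z3):
    """Boublik-Mansoori pair contact values g_ij^hs, full matrix."""
    mu = d[:, None] * d[None, :] / (d[:, None] + d[None, :])
    om = 1.0 - z3
    return 1.0 / om + mu * 3.0 * z2 / om**2 + mu**2 * 2.0 * z2**2 / om**3


def _delta_matrix(T, rho, x, ts):
    """Association strength Delta_AiBj in m^3 at the given density."""
    m, sig, u, d, sij, uij, epsij, kapij, kap = ts
    z0, z1, z2, z3 = _zeta(rho, x, m, d)
    gij = _g_contact(d, z2, z3)
    return sij**3 * gij * kapij * (np.exp(epsij / T) - 1.0)


def _solve_site_fractions(T, rho, x, ts):
    """Solve the 2B donor/acceptor site balances.

    Returns ``(XA, XB, delta)`` where XA/XB are per-component unbonded
    fractions.  Damped successive substitution with a Newton polish; the
    polish also drives the imaginary parts to convergence when the inputs
    carry a complex perturbation.
    """
    kap = ts[-1]
    n = len(kap)
    assoc = kap > 0.0
    delta = _delta_matrix(T, rho, x, ts)
    cplx = np.iscomplexobj(rho) or np.iscomplexobj(x)
    dtype = np.complex128 if cplx else np.float64
    XA = np.ones(n, dtype=dtype)
    XB = np.ones(n, dtype=dtype)
    XA[assoc] = 0.2
    XB[assoc] = 0.2
    rx = rho * np.asarray(x)
    D = delta * assoc[:, None] * assoc[None, :]

    def residual(XA, XB):
        rA = XA * (1.0 + D @ (rx * XB)) - 1.0
        rB = XB * (1.0 + D.T @ (rx * XA)) - 1.0
        rA[~assoc] = 0.0
        rB[~assoc] = 0.0
        return rA, rB

    # damped successive substitution to a loose tolerance; Newton finishes
    for _ in range(_ASSOC_SSI_ITER):
        XA_new = 1.0 / (1.0 + D @ (rx * XB))
        XB_new = 1.0 / (1.0 + D.T @ (rx * XA))
        XA_new[~assoc] = 1.0
        XB_new[~assoc] = 1.0
        step = max(np.max(np.abs(XA_new - XA)), np.max(np.abs(XB_new - XB)))
        XA = _ASSOC_DAMPING * XA + (1.0 - _ASSOC_DAMPING) * XA_new
        XB = _ASSOC_DAMPING * XB + (1.0 - _ASSOC_DAMPING) * XB_new
        if step < _ASSOC_SSI_TOL:
            break
    # Newton on the stacked site balances: quadratic convergence delivers the
    # final tolerance (and the complex-step imaginary parts) in a few steps.
    idx = np.flatnonzero(assoc)
    if idx.size:
        best = None
        for _ in range(12):
            rA, rB = residual(XA, XB)
            res = max(np.max(np.abs(rA)), np.max(np.abs(rB)))
            if res < 1.0e-16 or (best is not None and res >= best):
                break
            best = res
            nA = idx.size
            J = np.zeros((2 * nA, 2 * nA), dtype=dtype)
            F = np.concatenate([rA[idx], rB[idx]])
            # d rA_i / d XA_k and / d XB_k
            J[:nA, :nA] = np.diag(1.0 + (D @ (rx * XB))[idx])
            J[:nA, nA:] = XA[idx, None] * D[np.ix_(idx, idx)] * rx[idx][None, :]
            J[nA:, :nA] = XB[idx, None] * D.T[np.ix_(idx, idx)] * rx[idx][None, :]
            J[nA:, nA:] = np.diag(1.0 + (D.T @ (rx * XA))[idx])
            try:
                dX = np.linalg.solve(J, -F)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"association Newton step failed: {exc}") from exc
            XA[idx] += dX[:nA]
            XB[idx] += dX[nA:]
        rA, rB = residual(XA, XB)
        res = max(np.max(np.abs(rA)), np.max(np.abs(rB)))
        if res.real > _ASSOC_TOL:
            raise ConvergenceError("association site balance did not converge", float(res.real))
    return XA, XB, delta


# ---------------------------------------------------------------------------
# reduced residual Helmholtz energy


def _ares_parts(T, rho, x, ts):
    """(a_hc, a_disp, a_assoc), complex-safe in ``rho`` and ``x``."""
    m, sig, u, d, sij, uij, epsij, kapij, kap = ts
    x = np.asarray(x)
    mbar = np.sum(x * m)
    z0, z1, z2, z3 = _zeta(rho, x, m, d)
    _check_eta(z3)
    eta = z3
    om = 1.0 - z3
    a_hs = (
        3.0 * z1 * z2 / om + z2**3 / (z3 * om**2) + (z2**3 / z3**2 - z0) * np.log(om)
    ) / z0
    g_ii = np.diagonal(_g_contact(d, z2, z3))
    a_hc = mbar * a_hs - np.sum(x * (m - 1.0) * np.log(g_ii))

    xm = x * m
    m2es3 = np.sum(np.outer(xm, xm) * (uij / T) * sij**3)
    m2e2s3 = np.sum(np.outer(xm, xm) * (uij / T) ** 2 * sij**3)
    f1 = (mbar - 1.0) / mbar
    f2 = f1 * (mbar - 2.0) / mbar
    ab = _A[:, 0] + f1 * _A[:, 1] + f2 * _A[:, 2]
    bb = _B[:, 0] + f1 * _B[:, 1] + f2 * _B[:, 2]
    powers = eta ** np.arange(7)
    I1 = np.sum(ab * powers)
    I2 = np.sum(bb * powers)
    C1 = 1.0 / (
        1.0
        + mbar * (8.0 * eta - 2.0 * eta**2) / om**4
        + (1.0 - mbar)
        * (20.0 * eta - 27.0 * eta**2 + 12.0 * eta**3 - 2.0 * eta**4)
        / (om * (2.0 - eta)) ** 2
    )
    a_disp = -2.0 * np.pi * rho * I1 * m2es3 - np.pi * rho * mbar * C1 * I2 * m2e2s3

    if np.any(kap > 0.0):
        XA, XB, _ = _solve_site_fractions(T, rho, x, ts)
        assoc = kap > 0.0
        a_assoc = np.sum(
            x[assoc]
            * (
                np.log(XA[assoc])
                + np.log(XB[assoc])
                - 0.5 * (XA[assoc] + XB[assoc])
                + 1.0
            )
        )
    else:
        a_assoc = 0.0 * rho
    return a_hc, a_disp, a_assoc


def _ares(T, rho, x, ts):
    hc, disp, assoc = _ares_parts(T, rho, x, ts)
    return hc + disp + assoc


# ---------------------------------------------------------------------------
# public operations


def _require_rho(state: MixtureState) -> float:
    if state.rho is None:
        raise DomainError("state has no density; run solve_density first or set rho")
    return state.rho


def residual_helmholtz(state: MixtureState, params: ParameterSet) -> HelmholtzParts:
    """Reduced residual Helmholtz energy a_res/RT with named contributions."""
    rho = _require_rho(state)
    ts = _tstate(params, state.ids, state.T)
    hc, disp, assoc = _ares_parts(state.T, rho, np.asarray(state.x), ts)
    return HelmholtzParts(float(hc), float(disp), float(assoc))


def solve_association(state: MixtureState, params: ParameterSet) -> AssociationSolution:
    """Solve the 2B site balances at the state's density."""
    rho = _require_rho(state)
    ts = _tstate(params, state.ids, state.T)
    XA, XB, delta = _solve_site_fractions(state.T, rho, np.asarray(state.x), ts)
    X = {
        cid: {"A": float(XA[i]), "B": float(XB[i])}
        for i, cid in enumerate(state.ids)
    }
    return AssociationSolution(state.ids, X, delta)


def _Z(T, rho, x, ts) -> float:
    """Compressibility factor Z = 1 + eta d(a_res)/d(eta) by complex step."""
    h = rho * _COMPLEX_STEP
    da = _ares(T, rho + 1j * h, x, ts).imag / h
    return 1.0 + rho * da


def pressure_and_Z(state: MixtureState, params: ParameterSet) -> tuple[float, float]:
    """Pressure (Pa) and compressibility factor at the state's density."""
    rho = _require_rho(state)
    ts = _tstate(params, state.ids, state.T)
    Z = _Z(state.T, rho, np.asarray(state.x), ts)
    return Z * rho * KB * state.T, Z


def _packing_to_rho(eta: float, x, m, d) -> float:
    return 6.0 * eta / (np.pi * np.sum(x * m * d**3))


def _reduced_gibbs(T, rho, x, ts) -> float:
    """rho-dependent part of g/RT, used to rank root stability."""
    a = _ares(T, rho, x, ts)
    Z = _Z(T, rho, x, ts)
    return float(a + (Z - 1.0) - np.log(Z) + np.log(rho))


_ETA_SCAN_LO = 1.0e-10
_ETA_SCAN_HI = 0.7404


def solve_density(
    T: float,
    P: float,
    x: Mapping[str, float] | Sequence[float],
    params: ParameterSet,
    phase: str = "liquid",
    ids: Sequence[str] | None = None,
) -> MixtureState:
    """Solve P(rho) = P for the requested phase.

    ``x`` may be a mapping ``{component id: mole fraction}`` or a sequence
    aligned with ``ids``.  The liquid branch returns the highest-density
    root, the vapor branch the lowest; when several roots exist the returned
    state's ``stable`` flag marks whether it is the Gibbs-preferred one.
    """
    if T <= 0 or P <= 0:
        raise DomainError(f"T and P must be positive, got T={T}, P={P}")
    if phase not in ("liquid", "vapor"):
        raise DomainError(f"phase must be 'liquid' or 'vapor', got {phase!r}")
    if isinstance(x, Mapping):
        ids = tuple(x.keys())
        xv = np.array([x[c] for c in ids], dtype=float)
    else:
        if ids is None:
            raise DomainError("ids must accompany a sequence composition")
        ids = tuple(ids)
        xv = np.asarray(x, dtype=float)
    ts = _tstate(params, ids, T)
    m, sig, u, d = ts[0], ts[1], ts[2], ts[3]

    def pres(eta: float) -> float:
        rho = _packing_to_rho(eta, xv, m, d)
        return _Z(T, rho, xv, ts) * rho * KB * T - P

    etas = np.concatenate(
        [np.geomspace(_ETA_SCAN_LO, 1.0e-3, 8), np.linspace(2.0e-3, _ETA_SCAN_HI, 52)]
    )
    vals = np.array([pres(e) for e in etas])
    roots: list[float] = []
    for i in range(len(etas) - 1):
        if np.sign(vals[i]) != np.sign(vals[i + 1]):
            eta_root = brentq(pres, etas[i], etas[i + 1], xtol=1.0e-15, rtol=8.9e-16)
            roots.append(float(eta_root))
    if not roots:
        raise DensitySolveError(
            f"no {phase} density root at T={T} K, P={P} Pa", (_ETA_SCAN_LO, _ETA_SCAN_HI)
        )
    eta_sel = max(roots) if phase == "liquid" else min(roots)
    rho_sel = _packing_to_rho(eta_sel, xv, m, d)
    stable = True
    if len(roots) > 1:
        gibbs = [
            _reduced_gibbs(T, _packing_to_rho(e, xv, m, d), xv, ts) for e in roots
        ]
        stable = bool(np.argmin(gibbs) == roots.index(eta_sel))
    return MixtureState(
        T=T,
        ids=ids,
        x=tuple(float(v) for v in xv),
        P=P,
        rho=float(rho_sel),
        eta=float(eta_sel),
        phase=phase,
        stable=stable,
    )


def chemical_potentials_res(state: MixtureState, params: ParameterSet) -> dict[str, float]:
    """Residual chemical potentials mu_i^res/RT at constant T, V.

    Computed as d(n a_res)/dn_i by complex-step differentiation; the
    association solve is re-run at each perturbed composition, so the
    implicit dependence of the site fractions is included exactly.
    """
    rho = _require_rho(state)
    ts = _tstate(params, state.ids, state.T)
    xv = np.asarray(state.x, dtype=float)
    h = _COMPLEX_STEP
    mu = {}
    for i, cid in enumerate(state.ids):
        n = xv.astype(np.complex128)
        n[i] += 1j * h
        ntot = np.sum(n)
        # total moles scale the density at fixed volume
        g = ntot * _ares(state.T, ntot * rho, n / ntot, ts)
        mu[cid] = float(g.imag / h)
    return mu


def ln_fugacity_coefficients(
    T: float,
    P: float,
    x: Mapping[str, float] | Sequence[float],
    params: ParameterSet,
    phase: str = "liquid",
    ids: Sequence[str] | None = None,
) -> dict[str, float]:
    """ln phi_i at (T, P, x): mu_i^res/RT - ln Z at the solved phase density."""
    state = solve_density(T, P, x, params, phase=phase, ids=ids)
    mu = chemical_potentials_res(state, params)
    _, Z = pressure_and_Z(state, params)
    lnZ = np.log(Z)
    return {cid: mu[cid] - lnZ for cid in state.ids}
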