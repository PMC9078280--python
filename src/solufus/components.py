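"""Pure-component and binary PC-SAFT parameters.

A :class:`ComponentParameters` record holds one substance's segment number,
segment diameter, dispersion energy, association energy/volume and molar
mass.  The segment diameter may be a constant or a three-term exponential
temperature function

    sigma(T) = c0 + c1*exp(c2*T) + c3*exp(c4*T)      [angstrom, T in K]

which is the functional form used for water in aqueous-solution PC-SAFT
modelling.  Binary interactions carry a reference value at 298.15 K plus an
optional linear temperature slope,

    kij(T) = kij_ref + kij_slope*(T - 298.15).

Parameter sets are immutable (hashable) so that downstream computations can
cache reference-state results keyed on the parameter set itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .constants import T_REF_KIJ
from .errors import DomainError, SchemaError, UnknownComponentError, UnknownPairError

_SIGMA_RANGE = (273.0, 700.0)


@dataclass(frozen=True)
class SigmaModel:
    """Segment diameter in angstrom: constant, or three-term exponential in T."""

    c0: float
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0

    def __call__(self, T: float) -> float:
        if T <= 0:
            raise DomainError(f"temperature must be positive, got {T}")
        return self.c0 + self.c1 * math.exp(self.c2 * T) + self.c3 * math.exp(self.c4 * T)

    @property
    def is_constant(self) -> bool:
        return self.c1 == 0.0 and self.c3 == 0.0


@dataclass(frozen=True)
class ComponentParameters:
    """One component's PC-SAFT parameter set plus molar mass.

    Units: ``molar_mass`` g/mol, ``sigma`` angstrom, ``u_k`` and
    ``eps_assoc_k`` kelvin (energy/kB), ``kappa_assoc`` dimensionless.
    ``n_sites`` names the association scheme: ``"2B"`` (one donor + one
    acceptor site) or ``"none"``.
    """

    id: str
    molar_mass: float
    m_seg: float
    sigma: SigmaModel
    u_k: float
    eps_assoc_k: float = 0.0
    kappa_assoc: float = 0.0
    n_sites: str = "none"

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise SchemaError(f"{self.id}: molar_mass must be positive")
        if self.m_seg <= 0:
            raise SchemaError(f"{self.id}: m_seg must be positive")
        if self.u_k <= 0:
            raise SchemaError(f"{self.id}: u_k must be positive")
        if self.kappa_assoc < 0 or self.eps_assoc_k < 0:
            raise SchemaError(f"{self.id}: association parameters must be nonnegative")
        associating = self.kappa_assoc > 0
        if associating != (self.n_sites == "2B"):
            raise SchemaError(
                f"{self.id}: kappa_assoc {'> 0' if associating else '= 0'} requires "
                f"n_sites {'2B' if associating else 'none'}, got {self.n_sites!r}"
            )
        for T in _SIGMA_RANGE:
            if self.sigma(T) <= 0:
                raise SchemaError(f"{self.id}: sigma({T} K) must be positive")

    @property
    def associating(self) -> bool:
        return self.kappa_assoc > 0.0


def sigma_at(component: ComponentParameters, T: float) -> float:
    """Segment diameter of ``component`` at temperature ``T``, in angstrom."""
    return component.sigma(T)


@dataclass(frozen=True)
class BinaryInteraction:
    """Order-insensitive binary interaction parameter with linear T dependence."""

    pair: tuple[str, str]
    kij_ref: float
    kij_slope: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        if len(set(self.pair)) != 2:
            raise SchemaError(f"binary pair must name two distinct components, got {self.pair}")

    def kij(self, T: float) -> float:
        return self.kij_ref + self.kij_slope * (T - T_REF_KIJ)


def kij_at(pair: BinaryInteraction, T: float) -> float:
    """Binary interaction parameter of ``pair`` at temperature ``T``."""
    return pair.kij(T)


@dataclass(frozen=True)
class ParameterSet:
    """A validated collection of components and their binary interactions."""

    components: tuple[ComponentParameters, ...]
    binaries: tuple[BinaryInteraction, ...] = ()
    _by_id: Mapping[str, ComponentParameters] = field(
        init=False, repr=False, compare=False, hash=False, default=None
    )

    def __post_init__(self) -> None:
        by_id = {c.id: c for c in self.components}
        if len(by_id) != len(self.components):
            raise SchemaError("duplicate component ids in parameter set")
        for b in self.binaries:
            for cid in b.pair:
                if cid not in by_id:
                    raise UnknownComponentError(
                        f"binary interaction {b.pair} references undeclared component {cid!r}"
                    )
        pairs = [b.pair for b in self.binaries]
        if len(set(pairs)) != len(pairs):
            raise SchemaError("duplicate binary pairs in parameter set")
        object.__setattr__(self, "_by_id", by_id)

    def __getitem__(self, cid: str) -> ComponentParameters:
        try:
            return self._by_id[cid]
        except KeyError:
            raise UnknownComponentError(f"unknown component {cid!r}") from None

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.components)

    def binary(self, i: str, j: str) -> BinaryInteraction:
        key = tuple(sorted((i, j)))
        for b in self.binaries:
            if b.pair == key:
                return b
        raise UnknownPairError(f"no binary interaction declared for pair {key}")

    def kij(self, i: str, j: str, T: float, *, missing_as_zero: bool = False) -> float:
        """kij(T) for the (i, j) pair; symmetric in the component order.

        Undeclared pairs raise :class:`UnknownPairError` unless
        ``missing_as_zero`` is set explicitly.
        """
        if i == j:
            return 0.0
        try:
            return self.binary(i, j).kij(T)
        except UnknownPairError:
            if missing_as_zero:
                return 0.0
            raise

    def subset(self, ids: Iterable[str]) -> "ParameterSet":
        """A new parameter set restricted to ``ids`` (order preserved)."""
        ids = list(ids)
        comps = tuple(self[c] for c in ids)
        bins = tuple(b for b in self.binaries if all(c in ids for c in b.pair))
        return ParameterSet(comps, bins)

    def with_kij(self, i: str, j: str, kij_ref: float, kij_slope: float | None = None) -> "ParameterSet":
        """A copy with the (i, j) reference kij (and optionally slope) replaced."""
        key = tuple(sorted((i, j)))
        new_bins = []
        found = False
        for b in self.binaries:
            if b.pair == key:
                slope = b.kij_slope if kij_slope is None else kij_slope
                new_bins.append(BinaryInteraction(key, kij_ref, slope))
                found = True
            else:
                new_bins.append(b)
        if not found:
            new_bins.append(BinaryInteraction(key, kij_ref, kij_slope or 0.0))
        return ParameterSet(self.components, tuple(new_bins))


# ---------------------------------------------------------------------------
# serialization

_REQUIRED_FIELDS = ("molar_mass", "m_seg", "sigma", "u_k")


def _sigma_from_yaml(node) -> SigmaModel:
    if isinstance(node, (int, float)):
        return SigmaModel(float(node))
    if isinstance(node, dict):
        try:
            return SigmaModel(
                float(node["c0"]),
                float(node.get("c1", 0.0)),
                float(node.get("c2", 0.0)),
                float(node.get("c3", 0.0)),
                float(node.get("c4", 0.0)),
            )
        except KeyError as exc:
            raise SchemaError(f"sigma template missing field {exc.args[0]!r}") from None
    raise SchemaError(f"sigma must be a number or a coefficient mapping, got {type(node).__name__}")


def _sigma_to_yaml(model: SigmaModel):
    if model.is_constant:
        return model.c0
    return {"c0": model.c0, "c1": model.c1, "c2": model.c2, "c3": model.c3, "c4": model.c4}


def load_parameter_set(source: str | Path) -> ParameterSet:
    """Read a parameter file (YAML with ``components`` / ``binary_interactions``)."""
    text = Path(source).read_text()
    return parse_parameter_set(text)


def parse_parameter_set(text: str) -> ParameterSet:
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise SchemaError("parameter file must be a mapping at top level")
    comps = []
    for entry in doc.get("components", []) or []:
        if "id" not in entry:
            raise SchemaError("component entry missing field 'id'")
        for f in _REQUIRED_FIELDS:
            if f not in entry:
                raise SchemaError(f"component {entry['id']!r} missing field {f!r}")
        comps.append(
            ComponentParameters(
                id=str(entry["id"]),
                molar_mass=float(entry["molar_mass"]),
                m_seg=float(entry["m_seg"]),
                sigma=_sigma_from_yaml(entry["sigma"]),
                u_k=float(entry["u_k"]),
                eps_assoc_k=float(entry.get("eps_assoc_k", 0.0)),
                kappa_assoc=float(entry.get("kappa_assoc", 0.0)),
                n_sites=str(entry.get("n_sites", "none")),
            )
        )
    bins = []
    for entry in doc.get("binary_interactions", []) or []:
        if "pair" not in entry or "kij_ref" not in entry:
            raise SchemaError("binary interaction entry requires 'pair' and 'kij_ref'")
        pair = entry["pair"]
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise SchemaError(f"binary pair must list two component ids, got {pair!r}")
        bins.append(
            BinaryInteraction(
                pair=(str(pair[0]), str(pair[1])),
                kij_ref=float(entry["kij_ref"]),
                kij_slope=float(entry.get("kij_slope", 0.0)),
            )
        )
    return ParameterSet(tuple(comps), tuple(bins))


def dump_parameter_set(params: ParameterSet, target: str | Path | None = None) -> str:
    """Serialize ``params`` back to the YAML dialect read by :func:`load_parameter_set`."""
    doc = {
        "components": [
            {
                "id": c.id,
                "molar_mass": c.molar_mass,
                "m_seg": c.m_seg,
                "sigma": _sigma_to_yaml(c.sigma),
                "u_k": c.u_k,
                "eps_assoc_k": c.eps_assoc_k,
                "kappa_assoc": c.kappa_assoc,
                "n_sites": c.n_sites,
            }
            for c in params.components
        ],
        "binary_interactions": [
            {"pair": list(b.pair), "kij_ref": b.kij_ref, "kij_slope": b.kij_slope}
            for b in params.binaries
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if target is not None:
        Path(target).write_text(text)
    return text


def default_parameter_file() -> Path:
    """Path of the shipped aqueous amino-acid parameter fixture."""
    return Path(resources.files("solufus.data") / "table1.yaml")


def load_default_parameters() -> ParameterSet:
    """The shipped glycine / l-alanine / water parameter set."""
    return load_parameter_set(default_parameter_file())
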