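"""Exception hierarchy.

Every error raised by this package derives from :class:`SolufusError`, so
callers (and the CLI) can catch one base class.  Errors carry enough context
to diagnose the failing stage without re-running it.
"""

from __future__ import annotations


class SolufusError(Exception):
    """Base class for all package errors."""


class SchemaError(SolufusError):
    """A parameter or data file is missing a required field or is malformed."""


class UnknownComponentError(SolufusError):
    """A binary interaction references a component that was never declared."""


class UnknownPairError(SolufusError, KeyError):
    """A binary interaction was requested for an undeclared component pair."""


class DomainError(SolufusError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class PackingFractionError(SolufusError):
    """The segment packing fraction reached or exceeded the close-packing bound."""

    def __init__(self, eta: float, limit: float = 0.7405):
        self.eta = eta
        self.limit = limit
        super().__init__(f"packing fraction eta={eta:.6g} >= limit {limit}")


class ConvergenceError(SolufusError):
    """An iterative solver failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        if residual is not None:
            message = f"{message} (residual {residual:.3e})"
        super().__init__(message)


class DensitySolveError(SolufusError):
    """No density root was found for the requested phase.

    ``eta_range`` reports the packing-fraction interval that was scanned.
    """

    def __init__(self, message: str, eta_range: tuple[float, float]):
        self.eta_range = eta_range
        super().__init__(f"{message}; scanned eta in [{eta_range[0]:.3g}, {eta_range[1]:.3g}]")


class ReferenceStateError(SolufusError):
    """The pure hypothetical-liquid reference state could not be solved."""


class SLEError(SolufusError):
    """The saturation (solid-liquid equilibrium) iteration failed."""


class FitError(SolufusError):
    """A parameter fit failed; the message carries the optimizer trace."""


class MassLossError(SolufusError):
    """Heating and cooling heat-capacity curves disagree beyond tolerance."""


class NoPeakError(SolufusError):
    """No melting peak was found above the noise threshold."""


class AmbiguousPeakError(SolufusError):
    """Several comparable peaks were found; candidates are listed in kelvin."""

    def __init__(self, candidates: list[float]):
        self.candidates = candidates
        super().__init__(
            "multiple comparable peaks at T = "
            + ", ".join(f"{t:.1f} K" for t in candidates)
        )


class InsufficientDataError(SolufusError):
    """Too few observations for the requested regression."""


class IllConditionedFitError(SolufusError):
    """The regression design is degenerate (e.g. all sample masses equal)."""
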