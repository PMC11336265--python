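"""Exception hierarchy for the biosensor toolkit."""


class MetalsenseError(Exception):
    """Base class for all package-specific errors."""


class FixtureSpecError(MetalsenseError, ValueError):
    """Invalid placeholder-sequence specification (e.g. non-positive length)."""


class MissingPartError(MetalsenseError, KeyError):
    """A required standard part is absent from the registry."""

    def __init__(self, part_id: str):
        super().__init__(part_id)
        self.part_id = part_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"part {self.part_id!r} not found in registry"


class AssemblyGrammarError(MetalsenseError, ValueError):
    """Parts violate the promoter-RBS-CDS-terminator circuit grammar."""


class NumericalFailureError(MetalsenseError, ArithmeticError):
    """ODE integration failed or produced non-finite values."""


class CalibrationError(MetalsenseError, RuntimeError):
    """Threshold calibration could not bracket a dose-response flip."""


class StabilityError(MetalsenseError, ValueError):
    """Explicit diffusion step requested with dt above the stability bound."""


class OutOfDomainError(MetalsenseError, ValueError):
    """Concentration query outside the simulated spatial domain."""


class PlacementError(MetalsenseError, ValueError):
    """Initial population does not fit in the requested region."""


class ConfigError(MetalsenseError, ValueError):
    """Scenario configuration file is malformed or violates an invariant."""


class TimeSeriesError(MetalsenseError, ValueError):
    """Time-series records violate their invariants (empty, non-monotone...)."""
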