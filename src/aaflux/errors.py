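"""Exception hierarchy.

Schema/config problems and numerical problems are kept distinct so the CLI
can map them to different exit codes (2 and 3 respectively).
"""


class AAFluxError(Exception):
    """Base class for all package errors."""


class DomainError(AAFluxError, ValueError):
    """An input value is outside its physical or mathematical domain."""


class ConfigError(AAFluxError, ValueError):
    """Trial or simulation configuration is invalid or inconsistent."""


class SchemaError(AAFluxError, ValueError):
    """An input file does not match the expected tidy schema."""


class AlignmentError(AAFluxError, ValueError):
    """Time grids of jointly-used series do not line up."""

    def __init__(self, message: str, offending_times=None):
        super().__init__(message)
        self.offending_times = list(offending_times) if offending_times is not None else []


class PrecursorError(DomainError):
    """Precursor enrichment is zero/negative where a ratio requires it positive."""


class InfeasibleMixError(DomainError):
    """Requested mixture enrichment lies outside the feasible blend range."""


class SolverError(AAFluxError, RuntimeError):
    """Forward simulation failed to converge; carries the offending config."""

    def __init__(self, message: str, config=None):
        super().__init__(message)
        self.config = config
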