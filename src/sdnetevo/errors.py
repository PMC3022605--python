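"""Exception hierarchy for sdnetevo."""


class SdnetError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SdnetError, ValueError):
    """A model parameter is outside its admissible domain (h <= 0, non-finite x, ...)."""


class CatalogError(SdnetError, KeyError):
    """A genotype references an allele id that is not in the catalog."""


class ConvergenceError(SdnetError, RuntimeError):
    """The fixed-point solver or population recursion failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SexExtinctionError(SdnetError, RuntimeError):
    """All zygote mass of one sex vanished; the run is degenerate."""


class DegenerateBackgroundError(SdnetError, RuntimeError):
    """A background genotype's computed sex contradicts its ancestral role."""
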