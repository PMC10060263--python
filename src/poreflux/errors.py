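"""Exception hierarchy shared across the pipeline stages."""


class PorefluxError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(PorefluxError):
    """Input table does not match the expected column schema."""


class ValidationError(PorefluxError):
    """Input values violate a data-model invariant."""


class ConfigurationError(PorefluxError):
    """An option or solute name is not recognised."""


class ZoneError(PorefluxError):
    """A zonation prerequisite (e.g. a coherent nitrite interval) is missing."""


class GradientError(PorefluxError):
    """A gradient window cannot be formed."""


class FluxError(PorefluxError):
    """A flux computation prerequisite is missing; names the failing window."""


class SummaryError(PorefluxError):
    """Cross-site summary requested on an empty result set."""


class ScenarioError(PorefluxError):
    """A synthetic scenario is infeasible (negative concentrations, bad zones)."""


class PeakError(PorefluxError):
    """Abundance peak requested on an empty profile."""


class ConcordanceError(PorefluxError):
    """qPCR/amplicon comparison has no overlapping depths."""
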