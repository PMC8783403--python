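"""Exception hierarchy for equimeasure."""


class EquimeasureError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EquimeasureError):
    """A required column is missing or a schema map is malformed."""


class EmptyInputError(EquimeasureError):
    """An input file or population is empty where data is required."""


class ConfigurationError(EquimeasureError):
    """A simulation or pipeline configuration is invalid or incomplete."""


class DegenerateInputError(EquimeasureError):
    """Input carries no usable variation (e.g. an all-constant asset matrix)."""


class EstimationError(EquimeasureError):
    """A weighted estimate is undefined (empty record set, zero weight mass)."""


class MeasureError(EquimeasureError):
    """A summary measure is undefined (missing subgroup, zero denominator)."""


class SchemaCompatibilityError(EquimeasureError):
    """Two surveys use incompatible stratifier schemas (e.g. 5 vs 8 regions)."""


class PipelineError(EquimeasureError):
    """A pipeline stage failed; the message names the stage and survey."""
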