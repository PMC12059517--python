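"""Exception hierarchy for the LFQA pipeline."""


class LfqaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LfqaError):
    """A log/plan file does not conform to the documented dialect."""


class IntegrityError(LfqaError):
    """Internal consistency violated (duplicate spot keys, unpaired interlocks...)."""


class InvalidDataError(LfqaError):
    """Numerically or structurally invalid input data."""


class GeometryError(LfqaError):
    """Machine or grid geometry is unusable for the requested operation."""


class CoverageError(LfqaError):
    """A beam profile falls outside the instrumented strip range."""


class ConfigError(LfqaError):
    """Pipeline configuration fails schema validation."""


class InsufficientDataError(LfqaError):
    """Too few usable fractions for the requested statistic."""


class UndefinedCorrelationError(LfqaError):
    """Pearson correlation undefined (zero variance); reported as missing."""
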