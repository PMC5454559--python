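"""Exception hierarchy used across the package."""


class InsoleGaitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(InsoleGaitError, ValueError):
    """Input data or configuration violates an invariant."""


class ParseError(InsoleGaitError, ValueError):
    """On-disk representation is malformed."""


class DegenerateInputError(InsoleGaitError, ValueError):
    """Input is structurally valid but too small/empty for the operation."""


class UndefinedMetricError(InsoleGaitError, ValueError):
    """A metric has no defined value for this input (e.g. both-feet-zero symmetry)."""


class ConfigurationError(InsoleGaitError, ValueError):
    """A layout or pipeline configuration cannot support the requested operation."""
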