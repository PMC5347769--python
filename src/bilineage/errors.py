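"""Exception hierarchy shared across the package."""


class BilineageError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BilineageError, ValueError):
    """A parameter object violates one of its invariants."""


class InputValidationError(BilineageError, ValueError):
    """An input table or record violates the expected schema or ranges."""


class CalibrationError(BilineageError, ValueError):
    """Too little control data to calibrate thresholds or null statistics."""


class DegenerateInputError(BilineageError, ValueError):
    """A statistical comparison was requested on degenerate data."""
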