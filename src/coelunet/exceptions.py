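"""Exception types shared across the package."""


class CoelunetError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(CoelunetError, ValueError):
    """An invalid parameter or an inconsistent configuration."""


class FormatError(CoelunetError, ValueError):
    """An input file that does not match the expected layout."""


class InsufficientDataError(CoelunetError, ValueError):
    """Not enough observations (replicates, classes, pairs) to proceed."""
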