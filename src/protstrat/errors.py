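"""Exception types shared across the package."""


class ProtstratError(Exception):
    """Base class for package-specific errors."""


class ConfigError(ProtstratError, ValueError):
    """Invalid configuration or parameter value."""


class FormatError(ProtstratError, ValueError):
    """Malformed input file (missing column, bad value, wrong layout)."""


class CoverageError(ProtstratError, ValueError):
    """Too few signature proteins present in the target matrix."""
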