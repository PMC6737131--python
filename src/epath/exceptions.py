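"""Exception hierarchy shared across the package."""


class EPathError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EPathError, ValueError):
    """Input file violates the expected dialect (missing columns, bad XML, bad enum token)."""


class IntegrityError(EPathError, ValueError):
    """Input parses but violates a cross-record constraint (duplicate keys, dangling references)."""


class ConfigError(EPathError, ValueError):
    """A simulation or scoring configuration is invalid or infeasible."""
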