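"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes: input problems (2), bad
configuration (3), violated internal invariants (4).
"""


class SSETopoError(Exception):
    """Base class for all package-specific errors."""


class InputError(SSETopoError):
    """Unreadable, unparseable, or internally inconsistent input data."""


class ConfigError(SSETopoError):
    """Invalid configuration value or combination."""


class InvariantError(SSETopoError):
    """An internal contract was violated; indicates a bug, not bad input."""
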