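"""Exception hierarchy shared across the package.

Configuration problems (bad column maps, malformed YAML) and data problems
(unreadable tables, contract violations between runs) are distinguished so
the CLI can map them to distinct exit codes.
"""


class CetsaKitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CetsaKitError):
    """Invalid or incomplete configuration (missing columns, bad channel map)."""


class DataError(CetsaKitError):
    """Input data violates a precondition (too few values, unreadable file)."""


class ContractError(CetsaKitError):
    """Objects from incompatible runs/grids were combined."""


class DomainError(CetsaKitError, ValueError):
    """Numeric argument outside the mathematical domain (e.g. x <= 0)."""
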