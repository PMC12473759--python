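"""Exception hierarchy shared across the package."""


class AstwError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AstwError, ValueError):
    """A trial file does not declare the required columns."""


class ValidationError(AstwError, ValueError):
    """Input data violates a documented invariant (labels, shapes, finiteness)."""


class ConfigError(AstwError, ValueError):
    """A configuration value is out of range or inconsistent."""


class ContractError(AstwError, ValueError):
    """An operation was called with arguments outside its contract."""


class EmptyStreamError(AstwError, ValueError):
    """A trial is too short to produce a single analysis window."""


class InsufficientDataError(AstwError, ValueError):
    """A class has too few samples for the requested statistic."""


class StratificationError(AstwError, ValueError):
    """A training split is missing one or more required classes."""


class NumericError(AstwError, ArithmeticError):
    """A numerical routine produced a non-finite result."""
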