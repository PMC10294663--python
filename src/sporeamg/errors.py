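"""Exception hierarchy shared across the package."""


class SporeAmgError(Exception):
    """Base class for all package errors."""


class ValidationError(SporeAmgError):
    """A value violates a documented invariant (names the offending field)."""


class SchemaError(SporeAmgError):
    """An input table is missing required columns."""


class ReferentialIntegrityError(SporeAmgError):
    """A foreign key (phage_id, host_id) does not resolve; lists offenders."""
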