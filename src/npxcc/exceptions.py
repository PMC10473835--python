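"""Exception hierarchy.

User-facing errors derive from :class:`NpxccError`; the CLI maps them to
exit code 1 and anything else to exit code 2.
"""


class NpxccError(Exception):
    """Base class for all errors raised by npxcc."""


class SchemaError(NpxccError):
    """An input table is missing a required column or has the wrong type."""


class IntegrityError(NpxccError):
    """Input data violates a structural invariant (duplicates, bad joins)."""


class ConfigError(NpxccError):
    """A configuration value is missing, malformed or out of range."""
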