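"""Exception hierarchy shared across the package."""


class RvescoreError(Exception):
    """Base class for all package errors."""


class ConfigError(RvescoreError):
    """A configuration file is missing, unparseable, or internally inconsistent."""


class ValidationError(RvescoreError):
    """A domain object violates one of its invariants."""


class InputError(RvescoreError):
    """User-supplied variant or answer input is malformed."""


class SourceFormatError(RvescoreError):
    """An annotation source file is ill-formed (duplicate rows, bad columns...)."""


class ReportSchemaError(RvescoreError):
    """A report file does not match the schema version this build understands."""
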