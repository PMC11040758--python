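"""Exception hierarchy shared across the package."""


class SdiError(Exception):
    """Base class for all package errors."""


class SchemaError(SdiError):
    """An input table is missing a required column or has a bad dtype."""


class ReferentialError(SdiError):
    """A child table references a person_id absent from the persons table."""


class ConfigError(SdiError):
    """Invalid configuration value (unknown label, bad path, bad proportions)."""


class DomainError(SdiError):
    """A value violates an operation's mathematical preconditions."""


class DataError(SdiError):
    """A reference table (impact factors, crosswalk, cutpoints) is invalid."""


class DegenerateDesignError(SdiError):
    """Too little variation for the requested statistical operation."""


class RangeError(SdiError):
    """A questionnaire response lies outside its valid range."""
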