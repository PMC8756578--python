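"""Exception hierarchy shared across the pipeline stages."""


class CreatRefError(ValueError):
    """Base class for all pipeline errors."""


class ConfigurationError(CreatRefError):
    """A config value, column map, or method tag is invalid or missing."""


class ValidationError(CreatRefError):
    """Input rows violate the measurement-record invariants."""

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = list(issues) if issues is not None else []


class IntegrityError(CreatRefError):
    """Internal consistency broken: duplicate strata, overlapping windows,
    or a flow summary whose counts do not add up."""


class DomainError(CreatRefError):
    """An operation was called outside its mathematical domain
    (empty sample, negative SD, unpaired strata ...)."""


class GroupLookupError(CreatRefError, KeyError):
    """A requested age/sex stratum is not covered by the configuration."""
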