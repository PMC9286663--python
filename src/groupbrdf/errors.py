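"""Exception hierarchy shared by all modules."""


class GroupBrdfError(Exception):
    """Base class for all package errors."""


class FormatError(GroupBrdfError):
    """A file does not conform to the expected on-disk format."""


class IntegrityError(GroupBrdfError):
    """Header and binary payload are mutually inconsistent."""


class ConfigurationError(GroupBrdfError):
    """A run configuration or parameter value is invalid."""


class DataError(GroupBrdfError):
    """Input data violate a precondition (empty masks, bad ranges, ...)."""
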