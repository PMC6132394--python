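"""Exception hierarchy shared across the assessment library."""


class D9Error(Exception):
    """Base class for all library errors."""


class SchemaError(D9Error):
    """Input table is structurally invalid (e.g. a required column is missing)."""


class ValidationError(D9Error):
    """A record violates a domain invariant (range, sign, enumeration)."""


class DuplicateError(D9Error):
    """Two records claim the same (series key, year) slot with conflicting values."""


class LookupError_(D9Error):
    """A registry or table lookup found no entry (or too many)."""


class AmbiguityError(LookupError_):
    """A registry lookup matched more than one entry."""


class InsufficientDataError(D9Error):
    """A statistical procedure was given fewer points than it needs."""
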