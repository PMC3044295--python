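"""Exception hierarchy shared across the package."""


class PocketNetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PocketNetError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PocketNetError):
    """An input violated a structural invariant (bad index, bad value...)."""


class EmptyInputError(PocketNetError):
    """An operation received an empty collection where content is required."""


class MismatchError(PocketNetError):
    """Two objects that must refer to the same entity do not."""


class ConflictError(PocketNetError):
    """An annotation update collides with an existing known annotation."""


class LookupError_(PocketNetError):
    """An id was not found in the containing collection."""


class ConfigError(PocketNetError):
    """Infeasible or inconsistent configuration parameters."""


class NoAnchorError(PocketNetError):
    """No neighbor with a known or assumed interaction site exists, so no
    cluster satisfies the anchoring constraint.  This condition is expected
    during the first prediction round and drives the iterative complement
    loop rather than aborting a run."""
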