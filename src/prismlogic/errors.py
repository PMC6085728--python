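"""Exception hierarchy for prismlogic."""


class PrismlogicError(Exception):
    """Base class for all package errors."""


class DomainLookupError(PrismlogicError, KeyError):
    """A domain name is not registered in the architecture."""


class SpecError(PrismlogicError, ValueError):
    """An architecture or model parameter violates its invariants."""


class AssemblyError(PrismlogicError):
    """A face or prism could not be assembled from the given strands."""


class ClassificationError(PrismlogicError):
    """A complex could not be mapped onto a canonical prism state."""


class EngineError(PrismlogicError):
    """The reaction engine failed (e.g. the iteration guard tripped)."""


class GenerationError(PrismlogicError):
    """Sequence generation could not satisfy the design constraints."""


class InputError(PrismlogicError, ValueError):
    """A user-supplied value is outside its documented range."""


class DecodeError(PrismlogicError):
    """A final structure has no assigned logic output value."""
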