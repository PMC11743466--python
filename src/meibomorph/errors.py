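"""Exception hierarchy shared across the package."""


class MeibomorphError(Exception):
    """Base class for all package-specific errors."""


class InputError(MeibomorphError):
    """A file is missing, unreadable, or not in a supported format."""


class ValidationError(MeibomorphError):
    """A domain object violates one of its invariants."""


class DegenerateGlandError(MeibomorphError):
    """A gland is too small, too thin, or too pathological to measure.

    Callers that iterate over glands catch this and flag the gland rather
    than aborting the whole image.
    """


class SpacingError(MeibomorphError):
    """Requested synthetic gland layout would make glands overlap."""
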