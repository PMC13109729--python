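"""Exception hierarchy for hashdemux.

Validation failures raise the most specific subclass so callers (and the
CLI's exit-code mapping) can distinguish malformed inputs from runtime
problems.
"""


class HashdemuxError(Exception):
    """Base class for all hashdemux errors."""


class FormatError(HashdemuxError):
    """An input file violates its format contract (dimensions, duplicates...)."""


class AlignmentError(HashdemuxError):
    """Two paired inputs do not share the same barcodes/ordering."""


class DegenerateInputError(HashdemuxError):
    """The input is too degenerate for the requested operation
    (e.g. more clusters than distinct droplet profiles)."""


class InsufficientDataError(HashdemuxError):
    """Not enough observations to estimate the requested quantity."""


class ConflictError(HashdemuxError):
    """Two hashtags claim the same cluster and the conflict could not be
    resolved automatically; carries the hashtag names involved."""

    def __init__(self, message: str, hashtags=()):
        super().__init__(message)
        self.hashtags = tuple(hashtags)


class ConfigurationError(HashdemuxError):
    """A run configuration value is out of range or unknown."""
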