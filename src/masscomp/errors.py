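"""Exception hierarchy.

Every failure mode that can route a scan to the raw-fallback path has its own
class so the container can distinguish "fall back" from "abort".
"""


class MasscompError(Exception):
    """Base class for all masscomp errors."""


class PayloadError(MasscompError):
    """A peaks payload could not be base64-decoded."""


class PairsError(MasscompError):
    """A payload holds an odd number of words and cannot be split into pairs."""


class AlphabetError(MasscompError):
    """A symbol outside the declared alphabet was handed to the coder."""


class CoderError(MasscompError):
    """A symbol with zero frequency was handed to the arithmetic encoder."""


class TruncatedStreamError(MasscompError):
    """An arithmetic-coded payload ended before all symbols were decoded."""


class CorruptArchiveError(MasscompError):
    """Archive magic/version mismatch or truncated records."""


class CorruptBlockError(CorruptArchiveError):
    """A scan block's internal streams are inconsistent."""


class SelfCheckError(MasscompError):
    """Compression self-verification found a mismatch (never emitted to disk)."""
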