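"""Bit-exact handling of base64 peaks payloads.

mzXML stores each scan's (m/z, intensity) pairs as base64 text encoding
big-endian ("network" byte order) IEEE 754 words, single (32-bit) or double
(64-bit) precision depending on the scan's ``precision`` attribute.  All code
in this package manipulates the raw bit patterns as unsigned integers — a
word is never parsed into a Python float on the compression path, so NaN
payloads, signed zeros, infinities and denormals survive untouched.
"""

from __future__ import annotations

import base64
import binascii
import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import PairsError, PayloadError

__all__ = [
    "Precision",
    "PeaksPayload",
    "decode_payload",
    "encode_payload",
    "word_to_hex",
    "hex_to_word",
    "split_pairs",
    "interleave_pairs",
    "words_to_bytes",
    "bytes_to_words",
    "word_value",
]


class Precision(enum.Enum):
    """Word width of a peaks payload, from the scan's ``precision`` attribute."""

    SINGLE = 32
    DOUBLE = 64

    @property
    def width(self) -> int:
        """Bit width of one word (32 or 64)."""
        return self.value

    @property
    def n_bytes(self) -> int:
        return self.value // 8

    @property
    def hex_digits(self) -> int:
        return self.value // 4

    @property
    def dtype(self) -> np.dtype:
        """Big-endian unsigned dtype matching the on-wire word layout."""
        return np.dtype(">u4") if self is Precision.SINGLE else np.dtype(">u8")

    @classmethod
    def from_attribute(cls, text: str) -> "Precision":
        if text == "32":
            return cls.SINGLE
        if text == "64":
            return cls.DOUBLE
        raise ValueError(f"unsupported peaks precision attribute: {text!r}")


@dataclass(frozen=True)
class PeaksPayload:
    """One scan's decoded peaks element text.

    ``words`` are the whole big-endian words, ``pad_bytes`` any trailing bytes
    of the decoded binary not filling a whole word (preserved verbatim), and
    ``canonical`` records whether re-encoding words+pad reproduces
    ``base64_text`` character-for-character.  Non-canonical payloads (e.g.
    line-wrapped base64) are never normalized — the container stores them raw.
    """

    base64_text: str
    words: tuple[int, ...]
    pad_bytes: bytes
    precision: Precision
    canonical: bool

    @property
    def has_even_words(self) -> bool:
        return len(self.words) % 2 == 0


def words_to_bytes(words: Sequence[int] | np.ndarray, precision: Precision) -> bytes:
    """Concatenate words as big-endian bytes."""
    arr = np.asarray(words, dtype=np.uint64)
    return arr.astype(precision.dtype).tobytes()


def bytes_to_words(raw: bytes, precision: Precision) -> np.ndarray:
    """Inverse of :func:`words_to_bytes`; ``len(raw)`` must be a whole number of words."""
    if len(raw) % precision.n_bytes:
        raise ValueError("byte length is not a multiple of the word size")
    return np.frombuffer(raw, dtype=precision.dtype).astype(np.uint64)


def decode_payload(base64_text: str, precision: Precision) -> PeaksPayload:
    """Decode a peaks element's text into whole words plus trailing pad bytes.

    Whitespace is stripped before decoding (XML-insignificant), but its
    presence makes the payload non-canonical.  No information is discarded:
    ``words`` + ``pad_bytes`` reproduce the decoded binary exactly.
    """
    compact = "".join(base64_text.split())
    try:
        raw = base64.b64decode(compact.encode("ascii"), validate=True)
    except (binascii.Error, ValueError, UnicodeEncodeError) as exc:
        raise PayloadError(f"invalid base64 in peaks payload: {exc}") from exc
    nb = precision.n_bytes
    n_whole = len(raw) // nb
    words = tuple(int(w) for w in bytes_to_words(raw[: n_whole * nb], precision))
    pad = raw[n_whole * nb :]
    canonical = encode_payload(words, pad, precision) == base64_text
    return PeaksPayload(base64_text, words, pad, precision, canonical)


def encode_payload(
    words: Iterable[int], pad_bytes: bytes | None, precision: Precision
) -> str:
    """Canonical (RFC 4648, padded, unwrapped) base64 of words + trailing bytes."""
    raw = words_to_bytes(tuple(words), precision) + (pad_bytes or b"")
    return base64.b64encode(raw).decode("ascii")


def word_to_hex(w: int, precision: Precision) -> str:
    """Fixed-width uppercase hexadecimal rendering of a word."""
    if not 0 <= w < (1 << precision.width):
        raise ValueError(f"word 0x{w:X} out of range for {precision.name}")
    return format(w, f"0{precision.hex_digits}X")


def hex_to_word(h: str, precision: Precision) -> int:
    """Exact inverse of :func:`word_to_hex`."""
    if len(h) != precision.hex_digits:
        raise ValueError(
            f"expected {precision.hex_digits} hex digits, got {len(h)}"
        )
    return int(h, 16)


def split_pairs(payload: PeaksPayload) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Separate interleaved (m/z, intensity) words into the two streams.

    m/z words sit at even indices, intensities at odd; an odd word count means
    the payload does not hold whole pairs and raises :class:`PairsError`
    (the container then stores that scan raw).
    """
    if len(payload.words) % 2:
        raise PairsError(
            f"payload holds {len(payload.words)} words; cannot split into pairs"
        )
    return payload.words[0::2], payload.words[1::2]


def interleave_pairs(
    mz_words: Sequence[int], intensity_words: Sequence[int]
) -> tuple[int, ...]:
    """Inverse of :func:`split_pairs`."""
    if len(mz_words) != len(intensity_words):
        raise PairsError("m/z and intensity streams differ in length")
    out: list[int] = []
    for m, i in zip(mz_words, intensity_words):
        out.append(m)
        out.append(i)
    return tuple(out)


def word_value(w: int, precision: Precision) -> float:
    """Numeric value of a word via the explicit sign/exponent/fraction fields.

    Interpretive utility only (reporting, sanity checks) — the compression
    path never converts words to numbers.  Computed from first principles,
    e.g. for single precision ``(-1)^s (1 + f/2^23) 2^(e-127)``, so it serves
    as an independent cross-check of bit-cast decoding.  Raises for Inf/NaN
    exponents, which have no finite value.
    """
    if precision is Precision.SINGLE:
        exp_bits, frac_bits, bias = 8, 23, 127
    else:
        exp_bits, frac_bits, bias = 11, 52, 1023
    sign = w >> (exp_bits + frac_bits)
    e = (w >> frac_bits) & ((1 << exp_bits) - 1)
    frac = w & ((1 << frac_bits) - 1)
    if e == (1 << exp_bits) - 1:
        raise ValueError("Inf/NaN bit pattern has no finite numeric value")
    if e == 0:  # subnormal (or zero)
        mag = (frac / 2.0**frac_bits) * 2.0 ** (1 - bias)
    else:
        mag = (1.0 + frac / 2.0**frac_bits) * 2.0 ** (e - bias)
    return -mag if sign else mag
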