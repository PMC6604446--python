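"""Intensity stream codec: windowed bit-field matching.

Ion counts are neither smooth nor monotone, but the instrument's limited
dynamic range means the sign+exponent bits at the top of each word repeat
heavily, and finite detector precision leaves low-order fraction bits shared
between nearby values.  Each word is therefore matched against the 15 most
recent values on one of two bit fields:

* mode A — the first 8 bits only (top byte: sign + 7 exponent bits);
* mode B — the first 8 bits together with the last 16 bits (single
  precision) or the last 32 bits (double precision).

A match is recorded as a pointer 1..15 to the nearest window entry with equal
field bits, plus the residual (the non-matched bits) as nibbles; no match is
pointer 0 with the full word stored in the unmatched section.  Pointers are
arithmetic-coded per scan.  The mode is chosen per scan by simulating the
search over the first 50 values under each mode (independent windows) and
keeping whichever matches more, ties going to B (more matched bits means
smaller residuals at equal match counts).

The 50-value probe, 15-deep window and 8-bit primary field are fixed design
constants (exposed read-only below); a scan whose coded form would not beat
the raw words is stored raw.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import CorruptBlockError
from .ieee_words import Precision, bytes_to_words, words_to_bytes
from .mz_codec import pack_nibbles, unpack_nibbles
from .range_coder import CodedStream, deserialize_table, serialize_table

__all__ = [
    "PROBE_LENGTH",
    "WINDOW_SIZE",
    "MATCH_BITS",
    "MatchMode",
    "IntensityScanBlock",
    "select_mode",
    "find_match",
    "encode_intensity_scan",
    "decode_intensity_scan",
]

PROBE_LENGTH = 50  # values inspected to choose the match mode
WINDOW_SIZE = 15   # match search depth; pointers live in {0..15}
MATCH_BITS = 8     # primary matched field: the word's first byte


class MatchMode(Enum):
    A = "first8"
    B = "first8+last"

    def tail_bits(self, precision: Precision) -> int:
        """Low-order bits included in the match (mode B only)."""
        if self is MatchMode.A:
            return 0
        return 16 if precision is Precision.SINGLE else 32

    def residual_nibbles(self, precision: Precision) -> int:
        """Hex digits of the non-matched field stored per matched word."""
        return (precision.width - MATCH_BITS - self.tail_bits(precision)) // 4


def _match_key(w: int, mode: MatchMode, precision: Precision) -> tuple[int, int]:
    head = w >> (precision.width - MATCH_BITS)
    tail_bits = mode.tail_bits(precision)
    return head, (w & ((1 << tail_bits) - 1)) if tail_bits else 0


def _residual(w: int, mode: MatchMode, precision: Precision) -> int:
    tail = mode.tail_bits(precision)
    mid_bits = precision.width - MATCH_BITS - tail
    return (w >> tail) & ((1 << mid_bits) - 1)


def _rebuild(matched: int, residual: int, mode: MatchMode, precision: Precision) -> int:
    head = matched >> (precision.width - MATCH_BITS)
    tail_bits = mode.tail_bits(precision)
    tail = matched & ((1 << tail_bits) - 1) if tail_bits else 0
    return (head << (precision.width - MATCH_BITS)) | (residual << tail_bits) | tail


def find_match(
    window: Sequence[int], w: int, mode: MatchMode, precision: Precision
) -> int:
    """Pointer to the nearest window entry matching ``w``'s field bits; 0 if none.

    ``window`` is ordered most-recent-first; pointer 1 is the immediately
    previous value.  Entries beyond :data:`WINDOW_SIZE` are never matched.
    """
    key = _match_key(w, mode, precision)
    for dist, prev in enumerate(window[:WINDOW_SIZE], start=1):
        if _match_key(prev, mode, precision) == key:
            return dist
    return 0


def _count_matches(probe: Sequence[int], mode: MatchMode, precision: Precision) -> int:
    window: list[int] = []
    hits = 0
    for w in probe:
        if find_match(window, w, mode, precision):
            hits += 1
        window.insert(0, w)
        del window[WINDOW_SIZE:]
    return hits


def select_mode(words: Sequence[int], precision: Precision) -> MatchMode:
    """Probe the first min(50, n) values under both modes; more matches wins.

    Each candidate mode runs its own independent window over the probe.  Ties
    go to mode B; an empty scan defaults to mode A.
    """
    probe = list(words[:PROBE_LENGTH])
    if not probe:
        return MatchMode.A
    a = _count_matches(probe, MatchMode.A, precision)
    b = _count_matches(probe, MatchMode.B, precision)
    return MatchMode.A if a > b else MatchMode.B


@dataclass(frozen=True)
class IntensityScanBlock:
    """Compressed representation of one scan's intensity word stream."""

    n_values: int
    precision: Precision
    mode: MatchMode
    raw_fallback: bool
    raw_words: bytes = b""
    pointers: CodedStream | None = None
    residuals: bytes = b""
    n_residual_nibbles: int = 0
    unmatched: bytes = b""


def encode_intensity_scan(words, precision: Precision) -> IntensityScanBlock:
    """Encode one scan's intensity words with the windowed match search."""
    vals = [int(w) for w in words]
    n = len(vals)
    mode = select_mode(vals, precision)
    rn = mode.residual_nibbles(precision)

    # Nearest match within the window == most recent occurrence of the key,
    # provided it is at most WINDOW_SIZE back; a last-seen-index map gives the
    # same answer as scanning the window, in O(1) per word.
    last_seen: dict[tuple[int, int], int] = {}
    pointers: list[int] = []
    residual_digits: list[int] = []
    unmatched: list[int] = []
    for i, w in enumerate(vals):
        key = _match_key(w, mode, precision)
        j = last_seen.get(key, -1)
        if j >= 0 and i - j <= WINDOW_SIZE:
            pointers.append(i - j)
            r = _residual(w, mode, precision)
            for t in range(rn - 1, -1, -1):
                residual_digits.append((r >> (4 * t)) & 0xF)
        else:
            pointers.append(0)
            unmatched.append(w)
        last_seen[key] = i

    block = IntensityScanBlock(
        n, precision, mode, raw_fallback=False,
        pointers=CodedStream.from_symbols(pointers, WINDOW_SIZE + 1),
        residuals=pack_nibbles(np.asarray(residual_digits, dtype=np.uint8)),
        n_residual_nibbles=len(residual_digits),
        unmatched=words_to_bytes(unmatched, precision),
    )
    raw = IntensityScanBlock(
        n, precision, mode, raw_fallback=True,
        raw_words=words_to_bytes(vals, precision),
    )
    if len(serialize_intensity_block(block)) >= len(serialize_intensity_block(raw)):
        return raw
    return block


def decode_intensity_scan(block: IntensityScanBlock, precision: Precision) -> np.ndarray:
    """Exact inverse of :func:`encode_intensity_scan`."""
    n = block.n_values
    if block.raw_fallback:
        words = bytes_to_words(block.raw_words, precision)
        if len(words) != n:
            raise CorruptBlockError("raw intensity block length mismatch")
        return words
    mode = block.mode
    rn = mode.residual_nibbles(precision)
    pointers = block.pointers.decode()
    if len(pointers) != n:
        raise CorruptBlockError("pointer stream length mismatch")
    residuals = unpack_nibbles(block.residuals, block.n_residual_nibbles)
    unmatched = bytes_to_words(block.unmatched, precision)
    history: list[int] = []
    ri = 0
    ui = 0
    for p in pointers:
        if p == 0:
            if ui >= len(unmatched):
                raise CorruptBlockError("unmatched section exhausted")
            w = int(unmatched[ui])
            ui += 1
        else:
            if ri + rn > block.n_residual_nibbles:
                raise CorruptBlockError("residual section exhausted")
            r = 0
            for t in range(rn):
                r = (r << 4) | int(residuals[ri + t])
            ri += rn
            if p > len(history):
                raise CorruptBlockError("pointer reaches before the stream start")
            w = _rebuild(history[-p], r, mode, precision)
        history.append(w)
    if ui != len(unmatched) or ri != block.n_residual_nibbles:
        raise CorruptBlockError("unconsumed residual/unmatched data")
    return np.asarray(history, dtype=np.uint64)


def serialize_intensity_block(block: IntensityScanBlock) -> bytes:
    """Layout: n u32, flags u8 (bit0 raw, bit1 mode B), then the three sections."""
    flags = (1 if block.raw_fallback else 0) | (2 if block.mode is MatchMode.B else 0)
    out = bytearray(struct.pack(">IB", block.n_values, flags))
    if block.raw_fallback:
        out += block.raw_words
        return bytes(out)
    out += serialize_table(block.pointers.table)
    out += struct.pack(">I", len(block.pointers.payload))
    out += block.pointers.payload
    out += struct.pack(">I", block.n_residual_nibbles)
    out += block.residuals
    n_unmatched = len(block.unmatched) // block.precision.n_bytes
    out += struct.pack(">I", n_unmatched)
    out += block.unmatched
    return bytes(out)


def deserialize_intensity_block(buf: bytes, precision: Precision) -> IntensityScanBlock:
    """Inverse of :func:`serialize_intensity_block`; consumes the whole buffer."""
    try:
        n_values, flags = struct.unpack_from(">IB", buf, 0)
    except struct.error as exc:
        raise CorruptBlockError("truncated intensity block header") from exc
    mode = MatchMode.B if flags & 2 else MatchMode.A
    off = 5
    if flags & 1:
        raw = buf[off:]
        if len(raw) != n_values * precision.n_bytes:
            raise CorruptBlockError("raw intensity block size mismatch")
        return IntensityScanBlock(n_values, precision, mode, raw_fallback=True,
                                  raw_words=raw)
    table, off = deserialize_table(buf, off)
    (plen,) = struct.unpack_from(">I", buf, off)
    off += 4
    pointers = CodedStream(buf[off : off + plen], n_values, table)
    if len(pointers.payload) != plen:
        raise CorruptBlockError("truncated pointer payload")
    off += plen
    (n_res,) = struct.unpack_from(">I", buf, off)
    off += 4
    res_bytes = (n_res + 1) // 2
    residuals = buf[off : off + res_bytes]
    if len(residuals) != res_bytes:
        raise CorruptBlockError("truncated residual section")
    off += res_bytes
    (n_unmatched,) = struct.unpack_from(">I", buf, off)
    off += 4
    unmatched = buf[off:]
    if len(unmatched) != n_unmatched * precision.n_bytes:
        raise CorruptBlockError("unmatched section size mismatch")
    return IntensityScanBlock(
        n_values, precision, mode, raw_fallback=False,
        pointers=pointers, residuals=residuals, n_residual_nibbles=n_res,
        unmatched=unmatched,
    )
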