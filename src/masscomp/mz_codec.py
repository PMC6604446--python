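"""m/z stream codec: per-digit hexadecimal deltas + coded zero-run lengths.

Within a scan the m/z series is smooth and monotonically increasing, so
adjacent words share a long common hexadecimal prefix.  Each word is rendered
as fixed-width hex and differenced digit-by-digit modulo 16 against its
predecessor (the scan's first word against an implicit all-zero word).  The
mod-16 digitwise delta — no borrow, no carry — is exactly invertible and
makes the run of leading zero digits equal the shared prefix length, which is
the statistic the coder exploits: the front-zero run lengths (and, for
double precision, the trailing back-zero runs) are arithmetic-coded with a
per-scan table, and the remaining "core" digits are nibble-packed verbatim,
their distribution being too close to uniform to repay further modeling.

Scans are independent of each other, and a scan whose coded form would not be
smaller than the raw words is stored raw (``raw_fallback``), so the codec is
correct and never expansive-by-much on arbitrary input; monotonicity only
affects effectiveness.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .errors import CorruptBlockError
from .ieee_words import Precision, bytes_to_words, words_to_bytes
from .range_coder import CodedStream, build_table, deserialize_table, serialize_table

__all__ = [
    "DigitDelta",
    "MzScanBlock",
    "hex_delta",
    "hex_add",
    "encode_mz_scan",
    "decode_mz_scan",
    "pack_nibbles",
    "unpack_nibbles",
]


@dataclass(frozen=True)
class DigitDelta:
    """Digitwise mod-16 difference between two equal-width hex strings."""

    digits: tuple[int, ...]
    front: int  # leading zero digits
    back: int   # trailing zero digits after the front run (0 if all zero)

    @property
    def core(self) -> str:
        """Hex digits strictly between the front and back zero runs."""
        d = len(self.digits)
        return "".join(
            format(x, "X") for x in self.digits[self.front : d - self.back]
        )


def hex_delta(prev: str, cur: str, track_back: bool = False) -> DigitDelta:
    """Per-position (cur - prev) mod 16; no borrow between positions.

    ``track_back`` additionally measures the trailing zero run (used for
    double precision, where low-order digits of the delta are often zero);
    with it off, ``back`` is always 0.
    """
    if len(prev) != len(cur):
        raise ValueError("hex strings differ in width")
    digits = tuple((int(c, 16) - int(p, 16)) % 16 for p, c in zip(prev, cur))
    d = len(digits)
    front = 0
    while front < d and digits[front] == 0:
        front += 1
    back = 0
    if track_back and front < d:
        while digits[d - 1 - back] == 0:
            back += 1
    return DigitDelta(digits, front, back)


def hex_add(prev: str, delta: DigitDelta) -> str:
    """Exact inverse of :func:`hex_delta`: per-position (prev + delta) mod 16."""
    if len(prev) != len(delta.digits):
        raise ValueError("hex string and delta differ in width")
    return "".join(
        format((int(p, 16) + dd) % 16, "X") for p, dd in zip(prev, delta.digits)
    )


@dataclass(frozen=True)
class MzScanBlock:
    """Compressed representation of one scan's m/z word stream."""

    n_values: int
    precision: Precision
    raw_fallback: bool
    raw_words: bytes = b""
    front: CodedStream | None = None
    back: CodedStream | None = None
    core: bytes = b""
    n_core_digits: int = 0


def pack_nibbles(digits: np.ndarray) -> bytes:
    """Pack 4-bit symbols two per byte, high nibble first; odd count zero-padded."""
    arr = np.asarray(digits, dtype=np.uint8)
    if arr.size % 2:
        arr = np.concatenate([arr, np.zeros(1, dtype=np.uint8)])
    return ((arr[0::2] << 4) | arr[1::2]).tobytes()


def unpack_nibbles(buf: bytes, n: int) -> np.ndarray:
    """Inverse of :func:`pack_nibbles` for the first ``n`` nibbles."""
    if len(buf) * 2 < n:
        raise CorruptBlockError("nibble buffer shorter than declared count")
    b = np.frombuffer(buf, dtype=np.uint8)
    out = np.empty(len(buf) * 2, dtype=np.uint8)
    out[0::2] = b >> 4
    out[1::2] = b & 0x0F
    return out[:n]


def _digit_matrix(words: np.ndarray, precision: Precision) -> np.ndarray:
    d = precision.hex_digits
    shifts = (4 * (d - 1 - np.arange(d))).astype(np.uint64)
    return ((words[:, None] >> shifts[None, :]) & np.uint64(0xF)).astype(np.uint8)


def _delta_runs(
    words: np.ndarray, precision: Precision
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Delta matrix plus per-row front / back zero-run lengths."""
    d = precision.hex_digits
    digits = _digit_matrix(words, precision)
    prev = np.vstack([np.zeros((1, d), dtype=np.uint8), digits[:-1]])
    delta = ((digits.astype(np.int16) - prev.astype(np.int16)) % 16).astype(np.uint8)
    nz = delta != 0
    any_nz = nz.any(axis=1)
    front = np.where(any_nz, np.argmax(nz, axis=1), d).astype(np.int64)
    if precision is Precision.DOUBLE:
        last_nz = d - 1 - np.argmax(nz[:, ::-1], axis=1)
        back = np.where(any_nz, d - 1 - last_nz, 0).astype(np.int64)
    else:
        back = np.zeros(len(words), dtype=np.int64)
    return delta, front, back


def encode_mz_scan(mz_words, precision: Precision) -> MzScanBlock:
    """Encode one scan's m/z words (any input is valid; smoothness just helps)."""
    words = np.asarray(mz_words, dtype=np.uint64)
    n = len(words)
    d = precision.hex_digits
    if n == 0:
        empty = CodedStream(b"", 0, build_table([], d + 1))
        return MzScanBlock(
            0, precision, raw_fallback=False, front=empty,
            back=empty if precision is Precision.DOUBLE else None,
        )
    delta, front, back = _delta_runs(words, precision)
    cols = np.arange(d)
    mask = (cols[None, :] >= front[:, None]) & (cols[None, :] < (d - back)[:, None])
    core_digits = delta[mask]  # row-major: per value, in digit order
    front_stream = CodedStream.from_symbols(front.tolist(), d + 1)
    back_stream = (
        CodedStream.from_symbols(back.tolist(), d + 1)
        if precision is Precision.DOUBLE
        else None
    )
    block = MzScanBlock(
        n, precision, raw_fallback=False,
        front=front_stream, back=back_stream,
        core=pack_nibbles(core_digits), n_core_digits=int(core_digits.size),
    )
    raw = MzScanBlock(n, precision, raw_fallback=True,
                      raw_words=words_to_bytes(words, precision))
    return raw if len(serialize_mz_block(block)) >= len(serialize_mz_block(raw)) else block


def decode_mz_scan(block: MzScanBlock, precision: Precision) -> np.ndarray:
    """Exact inverse of :func:`encode_mz_scan` (byte-identical word stream)."""
    n = block.n_values
    if block.raw_fallback:
        words = bytes_to_words(block.raw_words, precision)
        if len(words) != n:
            raise CorruptBlockError("raw m/z block length mismatch")
        return words
    if n == 0:
        return np.zeros(0, dtype=np.uint64)
    d = precision.hex_digits
    front = np.asarray(block.front.decode(), dtype=np.int64)
    if len(front) != n:
        raise CorruptBlockError("front-run stream length mismatch")
    if precision is Precision.DOUBLE:
        back = np.asarray(block.back.decode(), dtype=np.int64)
        if len(back) != n:
            raise CorruptBlockError("back-run stream length mismatch")
    else:
        back = np.zeros(n, dtype=np.int64)
    k = d - front - back
    if k.min() < 0 or int(k.sum()) != block.n_core_digits:
        raise CorruptBlockError("core digit count inconsistent with run lengths")
    core = unpack_nibbles(block.core, block.n_core_digits)
    cols = np.arange(d)
    mask = (cols[None, :] >= front[:, None]) & (cols[None, :] < (d - back)[:, None])
    delta = np.zeros((n, d), dtype=np.uint8)
    delta[mask] = core
    # prefix-sum mod 16 per digit column inverts the per-row delta chain
    digits = (np.cumsum(delta.astype(np.int64), axis=0) % 16).astype(np.uint64)
    shifts = (4 * (d - 1 - np.arange(d))).astype(np.uint64)
    words = (digits << shifts[None, :]).sum(axis=1, dtype=np.uint64)
    return words


def serialize_mz_block(block: MzScanBlock) -> bytes:
    """Wire layout: n_values u32, flags u8 (bit0 raw), then streams (big-endian)."""
    out = bytearray(struct.pack(">IB", block.n_values, 1 if block.raw_fallback else 0))
    if block.raw_fallback:
        out += block.raw_words
        return bytes(out)
    out += serialize_table(block.front.table)
    out += struct.pack(">I", len(block.front.payload))
    out += block.front.payload
    if block.precision is Precision.DOUBLE:
        out += serialize_table(block.back.table)
        out += struct.pack(">I", len(block.back.payload))
        out += block.back.payload
    out += struct.pack(">I", block.n_core_digits)
    out += block.core
    return bytes(out)


def deserialize_mz_block(buf: bytes, precision: Precision) -> MzScanBlock:
    """Inverse of :func:`serialize_mz_block`; consumes the whole buffer."""
    try:
        n_values, flags = struct.unpack_from(">IB", buf, 0)
    except struct.error as exc:
        raise CorruptBlockError("truncated m/z block header") from exc
    off = 5
    if flags & 1:
        raw = buf[off:]
        if len(raw) != n_values * precision.n_bytes:
            raise CorruptBlockError("raw m/z block size mismatch")
        return MzScanBlock(n_values, precision, raw_fallback=True, raw_words=raw)
    table, off = deserialize_table(buf, off)
    (plen,) = struct.unpack_from(">I", buf, off)
    off += 4
    front = CodedStream(buf[off : off + plen], n_values, table)
    if len(front.payload) != plen:
        raise CorruptBlockError("truncated front-run payload")
    off += plen
    back = None
    if precision is Precision.DOUBLE:
        btable, off = deserialize_table(buf, off)
        (blen,) = struct.unpack_from(">I", buf, off)
        off += 4
        back = CodedStream(buf[off : off + blen], n_values, btable)
        if len(back.payload) != blen:
            raise CorruptBlockError("truncated back-run payload")
        off += blen
    (n_core,) = struct.unpack_from(">I", buf, off)
    off += 4
    core = buf[off:]
    if len(core) != (n_core + 1) // 2:
        raise CorruptBlockError("core nibble section size mismatch")
    return MzScanBlock(
        n_values, precision, raw_fallback=False,
        front=front, back=back, core=core, n_core_digits=n_core,
    )
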