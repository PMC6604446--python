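"""Static multi-symbol arithmetic coder.

The coder is deliberately non-adaptive: symbol frequencies are counted over
the exact stream to be coded and stored alongside the payload, so scans with
only a handful of symbols pay no model-learning penalty and unseen symbols
cannot occur at decode time.

The bitstream is produced by a byte-oriented range coder (32-bit range,
64-bit low accumulator with carry cache, 5-byte flush).  Byte renormalization
makes the encoder and decoder consume exactly the same number of bytes, so a
truncated payload is always detected rather than silently mis-decoded.  The
layout is frozen: identical (symbols, table) input yields identical bytes on
every platform.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlphabetError, CoderError, TruncatedStreamError

__all__ = [
    "MAX_TOTAL",
    "FrequencyTable",
    "CodedStream",
    "build_table",
    "ac_encode",
    "ac_decode",
    "serialize_table",
    "deserialize_table",
]

#: Cap on the frequency-table total.  Larger streams are scaled down
#: proportionally (nonzero counts floored at 1) so counts fit the 16-bit
#: serialization while keeping the coder's integer arithmetic exact.
MAX_TOTAL = 1 << 16

_TOP = 1 << 24  # renormalization threshold of the 32-bit range
_MASK32 = 0xFFFFFFFF


@dataclass(frozen=True)
class FrequencyTable:
    """Static symbol counts driving the coder; stored in the output."""

    counts: tuple[int, ...]
    cumulative: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("negative symbol count")
        cum = [0]
        for c in self.counts:
            cum.append(cum[-1] + c)
        object.__setattr__(self, "cumulative", tuple(cum))

    @property
    def alphabet_size(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return self.cumulative[-1]


def build_table(symbols: Sequence[int], alphabet_size: int) -> FrequencyTable:
    """Count symbol occurrences; scale down proportionally past :data:`MAX_TOTAL`.

    Scaling keeps every observed symbol's count at >= 1 so it remains
    encodable, and clamps each stored count to 65535 (u16 serialization).
    """
    arr = np.asarray(symbols, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= alphabet_size):
        raise AlphabetError(
            f"symbol outside alphabet [0, {alphabet_size})"
        )
    counts = np.bincount(arr, minlength=alphabet_size).astype(np.int64)
    total = int(counts.sum())
    if total > MAX_TOTAL:
        scaled = counts * MAX_TOTAL // total
        scaled[(counts > 0) & (scaled == 0)] = 1
        counts = scaled
    counts = np.minimum(counts, 0xFFFF)
    return FrequencyTable(tuple(int(c) for c in counts))


class _Encoder:
    """LZMA-style range encoder with deferred-carry byte output."""

    def __init__(self) -> None:
        self.low = 0
        self.range = _MASK32
        self.cache = 0
        self.cache_size = 1
        self.out = bytearray()

    def _shift_low(self) -> None:
        if self.low < 0xFF000000 or self.low > _MASK32:
            carry = self.low >> 32
            self.out.append((self.cache + carry) & 0xFF)
            for _ in range(self.cache_size - 1):
                self.out.append((0xFF + carry) & 0xFF)
            self.cache_size = 0
            self.cache = (self.low >> 24) & 0xFF
        self.cache_size += 1
        self.low = (self.low & 0x00FFFFFF) << 8

    def encode(self, start: int, freq: int, total: int) -> None:
        r = self.range // total
        self.low += r * start
        if start + freq == total:
            self.range -= r * start
        else:
            self.range = r * freq
        while self.range < _TOP:
            self.range = (self.range << 8) & _MASK32
            self._shift_low()

    def flush(self) -> bytes:
        for _ in range(5):
            self._shift_low()
        return bytes(self.out)


def ac_encode(symbols: Sequence[int], table: FrequencyTable) -> bytes:
    """Encode a symbol sequence; every symbol must have a nonzero count."""
    if len(symbols) == 0:
        return b""
    counts = table.counts
    cum = table.cumulative
    total = table.total
    enc = _Encoder()
    for s in symbols:
        f = counts[s]
        if f == 0:
            raise CoderError(f"symbol {s} has zero frequency in the table")
        enc.encode(cum[s], f, total)
    return enc.flush()


def ac_decode(payload: bytes, table: FrequencyTable, n_symbols: int) -> list[int]:
    """Exact inverse of :func:`ac_encode` given the same table and count."""
    if n_symbols == 0:
        return []
    total = table.total
    if total == 0:
        raise CoderError("cannot decode against an empty frequency table")
    counts = table.counts
    cum = list(table.cumulative)

    pos = 0
    n = len(payload)

    def next_byte() -> int:
        nonlocal pos
        if pos >= n:
            raise TruncatedStreamError("coded payload ended prematurely")
        b = payload[pos]
        pos += 1
        return b

    next_byte()  # initial cache byte, value irrelevant to the decoder
    code = 0
    for _ in range(4):
        code = (code << 8) | next_byte()
    range_ = _MASK32

    from bisect import bisect_right

    out: list[int] = []
    for _ in range(n_symbols):
        r = range_ // total
        f = min(code // r, total - 1)
        s = bisect_right(cum, f) - 1
        start = cum[s]
        freq = counts[s]
        code -= r * start
        if start + freq == total:
            range_ -= r * start
        else:
            range_ = r * freq
        while range_ < _TOP:
            range_ = (range_ << 8) & _MASK32
            code = ((code << 8) | next_byte()) & _MASK32
        out.append(s)
    return out


def serialize_table(table: FrequencyTable) -> bytes:
    """alphabet_size (u8) then one big-endian u16 count per symbol."""
    if table.alphabet_size > 255:
        raise ValueError("alphabet too large for serialization")
    return bytes([table.alphabet_size]) + struct.pack(
        f">{table.alphabet_size}H", *table.counts
    )


def deserialize_table(buf: bytes, offset: int = 0) -> tuple[FrequencyTable, int]:
    """Inverse of :func:`serialize_table`; returns (table, next offset)."""
    if offset >= len(buf):
        raise TruncatedStreamError("missing frequency table")
    size = buf[offset]
    end = offset + 1 + 2 * size
    if end > len(buf):
        raise TruncatedStreamError("truncated frequency table")
    counts = struct.unpack(f">{size}H", buf[offset + 1 : end])
    return FrequencyTable(counts), end


@dataclass(frozen=True)
class CodedStream:
    """An arithmetic-coded symbol stream together with its model."""

    payload: bytes
    n_symbols: int
    table: FrequencyTable

    @classmethod
    def from_symbols(cls, symbols: Sequence[int], alphabet_size: int) -> "CodedStream":
        table = build_table(symbols, alphabet_size)
        return cls(ac_encode(symbols, table), len(symbols), table)

    def decode(self) -> list[int]:
        return ac_decode(self.payload, self.table, self.n_symbols)

    @property
    def serialized_size(self) -> int:
        # table + u32 length prefix + payload
        return 1 + 2 * self.table.alphabet_size + 4 + len(self.payload)
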