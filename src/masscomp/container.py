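"""mzXML container: byte-exact split, codec dispatch, archive format.

The file is split *lexically*: the byte stream is scanned for
``<peaks ...>text</peaks>`` spans and only the text span of each is lifted
out; every other byte — whitespace, attribute order, encoding declaration —
stays verbatim in the skeleton.  A DOM parse/serialize round trip cannot
guarantee byte-identical output across pretty-printer dialects, and byte
exactness is this tool's contract, so no XML parser is involved.

Each lifted payload is either *coded* (base64-decoded, split into m/z and
intensity streams, each run through its codec) or stored *raw*
(DEFLATE-compressed verbatim text) when anything about it resists bit-exact
re-encoding: non-canonical base64, an odd word count, a non-network byte
order, an unknown precision, or a pre-compressed (``compressionType="zlib"``)
payload.  Compression always finishes with a decompress-and-compare
self-check, so a codec defect can only ever surface as a loud error, never as
silent data loss.

Archive layout (all integers big-endian)::

    magic "MZC1" | version u8 | u32 len | gzip(skeleton) | u32 n_records | records

where the skeleton serialization alternates literal byte runs and payload
placeholders, and each record is a length-prefixed scan record (see
``_encode_record``).  ``split_archive``/``join_archive`` expose the same
content as two files — gzipped metadata and the binary pair records.
"""

from __future__ import annotations

import gzip
import re
import struct
import zlib
from dataclasses import dataclass, field

from . import bench
from .errors import CorruptArchiveError, PayloadError, SelfCheckError
from .ieee_words import (
    Precision,
    decode_payload,
    encode_payload,
    interleave_pairs,
    split_pairs,
)
from .intensity_codec import (
    decode_intensity_scan,
    deserialize_intensity_block,
    encode_intensity_scan,
    serialize_intensity_block,
)
from .mz_codec import (
    decode_mz_scan,
    deserialize_mz_block,
    encode_mz_scan,
    serialize_mz_block,
)

__all__ = [
    "MAGIC",
    "VERSION",
    "PeaksSpan",
    "SkeletonDocument",
    "extract_peaks",
    "reassemble",
    "compress_file",
    "decompress_file",
    "split_archive",
    "join_archive",
    "compression_ratio",
    "gain",
]

MAGIC = b"MZC1"
VERSION = 1

# re-exported formula helpers (Table-style benchmarking lives in masscomp.bench)
compression_ratio = bench.compression_ratio
gain = bench.gain

_ATTR_RE = re.compile(rb'([A-Za-z_][\w:.-]*)\s*=\s*"([^"]*)"')


@dataclass(frozen=True)
class PeaksSpan:
    """One peaks element's text span and the attributes that govern its coding."""

    text: bytes  # verbatim bytes between <peaks ...> and </peaks>
    precision: str | None
    byte_order: str | None
    compression_type: str | None


@dataclass
class SkeletonDocument:
    """Alternating literal byte runs and payload placeholders, in file order.

    ``segments`` holds ``bytes`` (literal) or ``int`` (index into the payload
    list).  Splicing the payload texts back at their placeholders reproduces
    the original file bytes exactly.
    """

    segments: list = field(default_factory=list)

    def n_placeholders(self) -> int:
        return sum(1 for s in self.segments if isinstance(s, int))


def extract_peaks(data: bytes) -> tuple[SkeletonDocument, list[PeaksSpan]]:
    """Lift every ``<peaks ...>...</peaks>`` text span out of the byte stream.

    Self-closing peaks elements and an absent closing tag leave the bytes in
    the skeleton untouched; a file with no peaks elements yields a skeleton
    that is one literal segment (degenerate but valid).
    """
    skeleton = SkeletonDocument()
    payloads: list[PeaksSpan] = []
    pos = 0
    lit_start = 0
    n = len(data)
    while True:
        i = data.find(b"<peaks", pos)
        if i < 0:
            break
        after = data[i + 6 : i + 7]
        if after not in (b" ", b"\t", b"\n", b"\r", b">", b"/"):
            pos = i + 6  # e.g. <peaksCount...> — not the peaks element
            continue
        tag_end = data.find(b">", i)
        if tag_end < 0:
            break
        if data[tag_end - 1 : tag_end] == b"/":  # self-closing, no text
            pos = tag_end + 1
            continue
        close = data.find(b"</peaks", tag_end)
        if close < 0:
            break
        attrs = dict(
            (k.decode("ascii", "replace"), v.decode("ascii", "replace"))
            for k, v in _ATTR_RE.findall(data[i : tag_end + 1])
        )
        text = data[tag_end + 1 : close]
        skeleton.segments.append(data[lit_start : tag_end + 1])
        skeleton.segments.append(len(payloads))
        payloads.append(
            PeaksSpan(
                text=text,
                precision=attrs.get("precision"),
                byte_order=attrs.get("byteOrder"),
                compression_type=attrs.get("compressionType"),
            )
        )
        lit_start = close
        pos = close
    skeleton.segments.append(data[lit_start:])
    return skeleton, payloads


def reassemble(skeleton: SkeletonDocument, payload_texts: list[bytes]) -> bytes:
    """Splice payload texts back into the skeleton (inverse of extraction)."""
    parts = []
    for seg in skeleton.segments:
        parts.append(payload_texts[seg] if isinstance(seg, int) else seg)
    return b"".join(parts)


# --- scan records -----------------------------------------------------------

_CLASS_CODED = 0
_CLASS_RAW = 1


def _codable(span: PeaksSpan) -> tuple[Precision, "object"] | None:
    """Decide the coded route; return (precision, payload) or None for raw."""
    if span.compression_type not in (None, "none"):
        return None
    if span.byte_order not in (None, "network"):
        return None
    if span.precision not in ("32", "64"):
        return None
    try:
        text = span.text.decode("ascii")
    except UnicodeDecodeError:
        return None
    precision = Precision.from_attribute(span.precision)
    try:
        payload = decode_payload(text, precision)
    except PayloadError:
        return None
    if not payload.canonical or not payload.has_even_words:
        return None
    return precision, payload


def _encode_record(span: PeaksSpan) -> bytes:
    route = _codable(span)
    if route is None:
        blob = zlib.compress(span.text, 9)
        return struct.pack(">BI", _CLASS_RAW, len(blob)) + blob
    precision, payload = route
    mz_words, int_words = split_pairs(payload)
    mz_blob = serialize_mz_block(encode_mz_scan(mz_words, precision))
    int_blob = serialize_intensity_block(encode_intensity_scan(int_words, precision))
    head = struct.pack(
        ">BBB", _CLASS_CODED, precision.n_bytes, len(payload.pad_bytes)
    )
    body = (
        payload.pad_bytes
        + struct.pack(">I", len(mz_blob))
        + mz_blob
        + struct.pack(">I", len(int_blob))
        + int_blob
    )
    record = head + body
    # coded record must actually pay off against plain DEFLATE of the text
    raw_blob = zlib.compress(span.text, 9)
    raw_record = struct.pack(">BI", _CLASS_RAW, len(raw_blob)) + raw_blob
    return record if len(record) < len(raw_record) else raw_record


def _decode_record(buf: bytes, offset: int) -> tuple[bytes, int]:
    """Decode one scan record starting at ``offset``; return (text, next offset)."""
    try:
        cls = buf[offset]
    except IndexError as exc:
        raise CorruptArchiveError("truncated scan record") from exc
    try:
        if cls == _CLASS_RAW:
            (blen,) = struct.unpack_from(">I", buf, offset + 1)
            start = offset + 5
            blob = buf[start : start + blen]
            if len(blob) != blen:
                raise CorruptArchiveError("truncated raw scan record")
            return zlib.decompress(blob), start + blen
        if cls != _CLASS_CODED:
            raise CorruptArchiveError(f"unknown scan record class {cls}")
        nb, pad_len = struct.unpack_from(">BB", buf, offset + 1)
        precision = Precision.SINGLE if nb == 4 else Precision.DOUBLE
        off = offset + 3
        pad = buf[off : off + pad_len]
        off += pad_len
        (mlen,) = struct.unpack_from(">I", buf, off)
        off += 4
        mz_block = deserialize_mz_block(buf[off : off + mlen], precision)
        off += mlen
        (ilen,) = struct.unpack_from(">I", buf, off)
        off += 4
        int_block = deserialize_intensity_block(buf[off : off + ilen], precision)
        off += ilen
    except struct.error as exc:
        raise CorruptArchiveError("truncated scan record") from exc
    mz_words = decode_mz_scan(mz_block, precision)
    int_words = decode_intensity_scan(int_block, precision)
    words = interleave_pairs(
        [int(w) for w in mz_words], [int(w) for w in int_words]
    )
    text = encode_payload(words, pad, precision).encode("ascii")
    return text, off


# --- skeleton serialization -------------------------------------------------


def _serialize_skeleton(skeleton: SkeletonDocument) -> bytes:
    out = bytearray(struct.pack(">I", len(skeleton.segments)))
    for seg in skeleton.segments:
        if isinstance(seg, int):
            out += struct.pack(">BI", 1, seg)
        else:
            out += struct.pack(">BI", 0, len(seg))
            out += seg
    return bytes(out)


def _deserialize_skeleton(buf: bytes) -> SkeletonDocument:
    try:
        (n_segs,) = struct.unpack_from(">I", buf, 0)
        off = 4
        segments: list = []
        for _ in range(n_segs):
            kind, val = struct.unpack_from(">BI", buf, off)
            off += 5
            if kind == 1:
                segments.append(val)
            else:
                seg = buf[off : off + val]
                if len(seg) != val:
                    raise CorruptArchiveError("truncated skeleton literal")
                segments.append(seg)
                off += val
    except struct.error as exc:
        raise CorruptArchiveError("truncated skeleton") from exc
    return SkeletonDocument(segments)


# --- whole-file operations --------------------------------------------------


def compress_file(data: bytes, verify: bool = True) -> bytes:
    """Compress an mzXML byte stream into a self-describing archive.

    With ``verify`` (the default, and strongly recommended) the archive is
    decompressed and compared against the input before being returned;
    a mismatch raises :class:`SelfCheckError` naming the first divergent scan.
    """
    skeleton, payloads = extract_peaks(data)
    records = [_encode_record(span) for span in payloads]
    skeleton_gz = gzip.compress(_serialize_skeleton(skeleton), 9, mtime=0)
    out = bytearray(MAGIC)
    out.append(VERSION)
    out += struct.pack(">I", len(skeleton_gz))
    out += skeleton_gz
    out += struct.pack(">I", len(records))
    for rec in records:
        out += rec
    archive = bytes(out)
    if verify:
        restored = decompress_file(archive)
        if restored != data:
            for idx, (span, rec) in enumerate(zip(payloads, records)):
                text, _ = _decode_record(rec, 0)
                if text != span.text:
                    raise SelfCheckError(
                        f"scan payload {idx} failed to round-trip byte-exactly"
                    )
            raise SelfCheckError("skeleton failed to round-trip byte-exactly")
    return archive


def decompress_file(archive: bytes) -> bytes:
    """Reconstruct the original mzXML bytes from an archive."""
    if archive[:4] != MAGIC:
        raise CorruptArchiveError("bad archive magic")
    if archive[4:5] != bytes([VERSION]):
        raise CorruptArchiveError("unsupported archive version")
    try:
        (skel_len,) = struct.unpack_from(">I", archive, 5)
    except struct.error as exc:
        raise CorruptArchiveError("truncated archive header") from exc
    off = 9
    skeleton_gz = archive[off : off + skel_len]
    if len(skeleton_gz) != skel_len:
        raise CorruptArchiveError("truncated skeleton section")
    off += skel_len
    try:
        skeleton = _deserialize_skeleton(gzip.decompress(skeleton_gz))
    except (OSError, zlib.error) as exc:
        raise CorruptArchiveError("corrupt skeleton gzip stream") from exc
    try:
        (n_records,) = struct.unpack_from(">I", archive, off)
    except struct.error as exc:
        raise CorruptArchiveError("truncated record count") from exc
    off += 4
    texts: list[bytes] = []
    for _ in range(n_records):
        text, off = _decode_record(archive, off)
        texts.append(text)
    if skeleton.n_placeholders() != n_records:
        raise CorruptArchiveError("placeholder/record count mismatch")
    return reassemble(skeleton, texts)


def split_archive(archive: bytes) -> tuple[bytes, bytes]:
    """Split an archive into (metadata file, pairs file).

    The metadata file carries the gzipped skeleton, the pairs file the scan
    records; :func:`join_archive` restores the single-archive form.
    """
    if archive[:4] != MAGIC:
        raise CorruptArchiveError("bad archive magic")
    (skel_len,) = struct.unpack_from(">I", archive, 5)
    head_end = 9 + skel_len
    meta = b"MZCM" + archive[4:5] + archive[9:head_end]
    pairs = b"MZCP" + archive[4:5] + archive[head_end:]
    return meta, pairs


def join_archive(meta: bytes, pairs: bytes) -> bytes:
    """Inverse of :func:`split_archive`."""
    if meta[:4] != b"MZCM" or pairs[:4] != b"MZCP":
        raise CorruptArchiveError("bad two-file magic")
    if meta[4:5] != pairs[4:5]:
        raise CorruptArchiveError("two-file version mismatch")
    skeleton_gz = meta[5:]
    return (
        MAGIC
        + meta[4:5]
        + struct.pack(">I", len(skeleton_gz))
        + skeleton_gz
        + pairs[5:]
    )
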