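"""Benchmark helpers: compression ratio, gain, pairs-only measurements.

Metric conventions:

* compression ratio  C.R. = 100 − compressed_size · 100 / original_size
  (percent of the original removed; higher is better);
* gain of this codec over a baseline = 100 · (1 − our_size / baseline_size).

The pairs-only harness measures exactly what the specialized codecs act on —
the decoded binary (m/z, intensity) words of every scan, padding bytes
included — against a gzip baseline applied to the same raw pairs bytes.
"""

from __future__ import annotations

import gzip as _gzip
from dataclasses import dataclass

__all__ = [
    "compression_ratio",
    "gain",
    "PairsBenchResult",
    "bench_pairs",
    "bench_whole_file",
    "format_report",
]


def compression_ratio(original_size: float, compressed_size: float) -> float:
    """Percent size reduction: ``100 - compressed_size*100/original_size``."""
    if original_size <= 0:
        raise ValueError("compression ratio undefined for non-positive original size")
    return 100.0 - compressed_size * 100.0 / original_size


def gain(our_size: float, other_size: float) -> float:
    """Percent improvement over a competing size: ``100*(1 - our/other)``."""
    if other_size <= 0:
        raise ValueError("gain undefined for non-positive baseline size")
    return 100.0 * (1.0 - our_size / other_size)


@dataclass(frozen=True)
class PairsBenchResult:
    """Sizes (bytes) and derived metrics for one file's numerical pairs."""

    name: str
    pairs_size: int
    coded_size: int
    gzip_size: int

    @property
    def coded_ratio(self) -> float:
        return compression_ratio(self.pairs_size, self.coded_size)

    @property
    def gzip_ratio(self) -> float:
        return compression_ratio(self.pairs_size, self.gzip_size)

    @property
    def gain_vs_gzip(self) -> float:
        return gain(self.coded_size, self.gzip_size)


def bench_pairs(data: bytes, name: str = "") -> PairsBenchResult:
    """Measure pairs-only compression of ``data`` (an mzXML byte stream)."""
    from . import container
    from .errors import PayloadError
    from .ieee_words import Precision, decode_payload, words_to_bytes

    _, payloads = container.extract_peaks(data)
    raw_parts: list[bytes] = []
    coded = 0
    for span in payloads:
        coded += len(container._encode_record(span))
        # raw binary size of the numerical data (padding included)
        prec = Precision.SINGLE if span.precision != "64" else Precision.DOUBLE
        try:
            p = decode_payload(span.text.decode("ascii", "replace"), prec)
            raw_parts.append(words_to_bytes(p.words, prec) + p.pad_bytes)
        except PayloadError:
            raw_parts.append(span.text)
    raw = b"".join(raw_parts)
    if not raw:
        raise ValueError("file contains no peaks data to benchmark")
    return PairsBenchResult(
        name=name,
        pairs_size=len(raw),
        coded_size=coded,
        gzip_size=len(_gzip.compress(raw, 9)),
    )


def bench_whole_file(data: bytes, name: str = "") -> PairsBenchResult:
    """Measure whole-file compression (archive vs gzip of the full file)."""
    from . import container

    return PairsBenchResult(
        name=name,
        pairs_size=len(data),
        coded_size=len(container.compress_file(data)),
        gzip_size=len(_gzip.compress(data, 9)),
    )


def format_report(results: list[PairsBenchResult]) -> str:
    """Render results as an aligned text table with sizes, C.R. and gain."""
    header = f"{'file':<24}{'size':>12}{'coded':>12}{'gzip':>12}{'C.R.':>8}{'C.R.gz':>8}{'gain':>8}"
    lines = [header, "-" * len(header)]
    for r in results:
        lines.append(
            f"{r.name:<24}{r.pairs_size:>12}{r.coded_size:>12}{r.gzip_size:>12}"
            f"{r.coded_ratio:>8.2f}{r.gzip_ratio:>8.2f}{r.gain_vs_gzip:>8.2f}"
        )
    return "\n".join(lines)
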