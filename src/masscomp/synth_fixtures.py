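"""Synthetic mzXML generation.

Emits minimal but schema-shaped mzXML files whose peak data carries the two
statistical properties the codecs exploit, without copying any real
spectrum:

* m/z series are strictly increasing and smooth — a random start value plus
  cumulative sums of positive log-normal increments, so adjacent words share
  long hexadecimal prefixes (profile-like specs use small fractional steps,
  centroid-like specs coarser ones);
* intensities are log-uniform within a bounded dynamic range, emulating a
  detector's limited range: the sign+exponent byte takes only a few distinct
  values, so windowed first-byte matching succeeds on most words, while the
  mantissa bits stay effectively random.

What these fixtures deliberately do *not* model: isotope envelopes, charge
states, peak shapes, scan metadata richness, or vendor pretty-printing.  They
exercise the codecs' assumptions, not mass-spectrometric realism.

``corrupt_fixture`` applies named adversarial mutations (odd word counts,
pre-compressed payloads, line-wrapped base64, empty peaks) that must all
survive the container's fallback paths byte-exactly.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass

import numpy as np

from .ieee_words import Precision

__all__ = ["FixtureSpec", "generate_mzxml", "corrupt_fixture", "CORRUPTION_KINDS"]

CORRUPTION_KINDS = ("odd-words", "zlib-attr", "wrapped-base64", "empty-peaks")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic file; same spec + seed => identical bytes.

    ``scan_kind`` selects the pairs-per-scan regime: ``"centroid"`` draws
    peak-picked scan sizes (tens to hundreds of pairs), ``"profile"``
    continuous-mode sizes (around ten thousand pairs).  ``mz_step`` is the
    mean m/z increment in Th; ``noise`` the log-normal sigma of the
    increments.  ``intensity_range`` bounds the detector dynamic range.
    """

    n_scans: int = 10
    scan_kind: str = "centroid"  # "centroid" | "profile"
    precision: Precision = Precision.SINGLE
    mz_start_range: tuple[float, float] = (100.0, 600.0)
    mz_step: float | None = None  # default per scan_kind
    noise: float = 0.3
    intensity_range: tuple[float, float] = (1.0e4, 1.0e6)
    seed: int = 0

    def pairs_per_scan(self, rng: np.random.Generator) -> int:
        if self.scan_kind == "profile":
            return int(rng.integers(6000, 12000))
        if self.scan_kind == "centroid":
            return int(rng.integers(20, 800))
        raise ValueError(f"unknown scan kind: {self.scan_kind!r}")

    @property
    def default_step(self) -> float:
        # profile mode samples the m/z axis densely; centroid spacing is the
        # gap between picked peaks
        return 0.002 if self.scan_kind == "profile" else 0.7


def _scan_words(spec: FixtureSpec, rng: np.random.Generator, n_pairs: int) -> bytes:
    step = spec.mz_step if spec.mz_step is not None else spec.default_step
    start = rng.uniform(*spec.mz_start_range)
    increments = np.exp(rng.normal(np.log(step), spec.noise, size=n_pairs))
    mz = start + np.cumsum(increments)
    lo, hi = spec.intensity_range
    intensity = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_pairs))
    if spec.precision is Precision.SINGLE:
        fdtype = np.dtype(">f4")
    else:
        fdtype = np.dtype(">f8")
    interleaved = np.empty(2 * n_pairs, dtype=fdtype)
    interleaved[0::2] = mz
    interleaved[1::2] = intensity
    return interleaved.tobytes()


def generate_mzxml(spec: FixtureSpec) -> bytes:
    """Render the spec as a minimal mzXML byte stream (canonical base64 peaks)."""
    rng = np.random.default_rng(spec.seed)
    prec_attr = "32" if spec.precision is Precision.SINGLE else "64"
    parts = [
        b'<?xml version="1.0" encoding="ISO-8859-1"?>\n',
        b'<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n',
        f' <msRun scanCount="{spec.n_scans}">\n'.encode(),
    ]
    for i in range(spec.n_scans):
        n_pairs = spec.pairs_per_scan(rng)
        raw = _scan_words(spec, rng, n_pairs)
        b64 = base64.b64encode(raw).decode("ascii")
        parts.append(
            f'  <scan num="{i + 1}" msLevel="1" peaksCount="{n_pairs}">\n'
            f'   <peaks precision="{prec_attr}" byteOrder="network"'
            f' contentType="m/z-int" compressionType="none">{b64}</peaks>\n'
            f"  </scan>\n".encode()
        )
    parts.append(b" </msRun>\n</mzXML>\n")
    return b"".join(parts)


def corrupt_fixture(mzxml_bytes: bytes, kind: str) -> bytes:
    """Apply a named adversarial mutation to the first peaks element.

    Every mutation leaves a file the container must still round-trip
    byte-exactly through its fallback paths.
    """
    from .container import extract_peaks, reassemble

    if kind not in CORRUPTION_KINDS:
        raise ValueError(f"unknown corruption kind: {kind!r}")
    if kind == "zlib-attr":
        return mzxml_bytes.replace(
            b'compressionType="none"', b'compressionType="zlib"', 1
        )
    skeleton, payloads = extract_peaks(mzxml_bytes)
    if not payloads:
        raise ValueError("fixture has no peaks payloads to corrupt")
    texts = [p.text for p in payloads]
    first = texts[0]
    if kind == "odd-words":
        prec = Precision.SINGLE if payloads[0].precision != "64" else Precision.DOUBLE
        raw = base64.b64decode(first) + b"\x3f\x80\x00\x00" * (prec.n_bytes // 4)
        texts[0] = base64.b64encode(raw)
    elif kind == "wrapped-base64":
        mid = max(1, len(first) // 2)
        texts[0] = first[:mid] + b"\n" + first[mid:]
    elif kind == "empty-peaks":
        texts[0] = b""
    return reassemble(skeleton, texts)
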