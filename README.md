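# masscomp

Lossless compression for mzXML mass-spectrometry files, specialized for the
base64-encoded (m/z, intensity) peak arrays that account for most of their
size.

## The problem

Proteomics and metabolomics pipelines store spectra in mzXML: XML metadata
wrapped around per-scan `<peaks>` elements whose text is base64-encoded,
big-endian IEEE 754 words — interleaved (m/z, intensity) pairs, single or
double precision per the scan's `precision` attribute. Repositories keep
these files uncompressed, and general-purpose compressors do poorly on
floating-point payloads. Lossy numerical codecs exist but cannot restore
double-precision data exactly. `masscomp` compresses the numerical pairs
with codecs that exploit their actual statistics, gzips everything else, and
reconstructs the original file **byte-for-byte** — including NaN bit
patterns, padding bytes and XML whitespace.

## The method

All processing operates on raw bit patterns (words are never parsed into
floats), so losslessness holds for every representable pattern.

**m/z stream** — within a scan, m/z values are smooth and monotonically
increasing, so consecutive words share a long hexadecimal prefix. Each word
is rendered as 8 (or 16) hex digits and differenced digit-by-digit modulo 16
against its predecessor:

    Δᵢ = (curᵢ − prevᵢ) mod 16,  i = 1..d

The run of leading zero digits of Δ equals the shared prefix length; these
front-zero run lengths (and, for double precision, the trailing back-zero
runs) are compressed with a static arithmetic coder whose frequency table is
stored per scan, and the remaining "core" digits — close to uniform — are
nibble-packed raw.

**Intensity stream** — ion counts are non-monotone, but the instrument's
bounded dynamic range makes the sign+exponent byte repeat heavily. Each word
is matched against the 15 most recent values on either its first 8 bits
(mode A) or its first 8 plus last 16/32 bits (mode B; the mode is chosen per
scan by probing the first 50 values). A hit emits a pointer 1–15 plus the
residual bits; a miss emits pointer 0 and the full word. Pointers are
arithmetic-coded.

**Container** — the file is split lexically at the byte level (no DOM round
trip), payloads that resist exact re-encoding (line-wrapped base64, odd word
counts, `compressionType="zlib"`, non-network byte order) are stored
DEFLATE-compressed verbatim, the XML skeleton is gzipped, and every
compression run ends with an internal decompress-and-compare self-check.

## Worked example

```
$ masscomp synth --scans 4 --pairs profile --seed 11 -o demo.mzXML
demo.mzXML: 4 profile scans, 366760 bytes
$ masscomp compress demo.mzXML -o demo.mzc
demo.mzXML: 366760 -> 161665 bytes (C.R. 55.92%)
$ masscomp decompress demo.mzc -o demo.back.mzXML
demo.back.mzXML: 366760 bytes restored
$ masscomp verify demo.mzXML
demo.mzXML: OK (byte-exact)
$ masscomp bench demo.mzXML
file                            size       coded        gzip    C.R.  C.R.gz    gain
------------------------------------------------------------------------------------
demo.mzXML                    274480      161336      224258   41.22   18.30   28.06
```

The synthetic file holds four profile-mode scans (~9000 pairs each, single
precision). Compression removes 55.92% of the whole file. The bench line
looks only at the numerical pairs (274,480 bytes of raw words): the
specialized codecs remove 41.22% versus gzip's 18.30% on the same bytes — a
28.06% size gain over gzip. Compression ratio is
`100 − compressed·100/original`; gain is `100·(1 − ours/gzip)`. Decompression
is verified byte-exact.

The same operations are available as library calls:

```python
from masscomp import compress_file, decompress_file
archive = compress_file(data)          # self-verified
assert decompress_file(archive) == data
```

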