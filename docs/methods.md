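# Methods

## Scope and contract

`masscomp` compresses mzXML files such that decompression reproduces the
input byte-for-byte. The contract is absolute: every compression run ends
with an internal decompress-and-compare self-check, so any codec defect
surfaces as a `SelfCheckError` rather than data loss. Scans are mutually
independent; any scan that resists bit-exact re-encoding is stored raw
(DEFLATE of the verbatim element text), so correctness never depends on the
statistical assumptions below — only effectiveness does.

## Word handling

Peaks payloads are decoded from base64 into raw 32- or 64-bit big-endian
words kept as unsigned integers end to end. Parsing into floats is never on
the compression path; NaN payloads, signed zeros, infinities and denormals
round-trip unchanged (property-tested over random and special bit
patterns). Trailing bytes that do not fill a whole word ("padding") are
preserved verbatim in the scan record. A payload is only eligible for the
specialized codecs when its base64 is *canonical* — re-encoding the decoded
bytes reproduces the text exactly. Line-wrapped or otherwise non-canonical
base64 is detected, never normalized, and routed to the raw path; modeling
every pretty-printer dialect would buy little and risk the byte-exactness
contract.

`ieee_words.word_value` exposes the explicit sign/exponent/fraction
evaluation of a word (e.g. `(-1)^s (1 + f/2^23) 2^(e-127)` for single
precision). It exists for reporting and as an independent cross-check of
bit-cast decoding in the tests; codecs never call it.

## m/z codec

Adjacent m/z values within a scan are smooth and monotonically increasing,
so their fixed-width hex renderings share long prefixes. The codec
differences each word against its predecessor *per hex digit, modulo 16,
with no borrow*. This choice is load-bearing: digitwise mod-16 subtraction
is exactly invertible by digitwise addition, is positional, and makes the
delta's leading-zero run equal the shared-prefix length. Integer
subtraction with borrow was rejected because a borrow can destroy the
leading-zero run (e.g. crossing a power of two). A consequence worth noting:
on an integer ramp w, w+1, w+2, … the front run is 7 of 8 digits only until
the low digit wraps; the carry step touches two digits. The codec does not
care — run lengths are data, not assumptions.

Each scan's first word is differenced against an implicit all-zero
predecessor, keeping scans self-contained (a prerequisite for future
per-scan random access). Front-zero run lengths (alphabet 0..8 or 0..16) are
arithmetic-coded; for double precision the trailing back-zero run of the
remaining digits is coded the same way (back ≡ 0 when the delta is entirely
zero). Core digits between the runs are packed two per byte — empirically
near-uniform, so further modeling would not pay. Frequency tables are built
per scan and stored in the block header: scans range from a few pairs to
tens of thousands, and an adaptive coder would waste its learning phase on
the small ones.

## Intensity codec

Intensities are non-monotone but range-limited: the top byte (sign + 7
exponent bits) takes few distinct values, and finite detector precision
leaves low-order fraction bits correlated. Each word is matched against the
15 most recent values (pointer alphabet {0..15}, 0 = no match) on one of two
fields: mode A, the first 8 bits; mode B, the first 8 plus the last 16
(single) or 32 (double) bits. Matching 8 rather than 9 bits keeps the match
field byte-aligned. The mode is selected per scan by simulating the search
over the first min(50, n) values under each mode with independent windows
and keeping the one with more matches; ties go to B because more matched
bits mean smaller residuals at equal match count. The scan proper is then
encoded from scratch in the chosen mode. Matches take the *nearest*
candidate, skewing the pointer distribution toward small values, which the
arithmetic coder converts into fewer bits. Residuals (the unmatched middle
or trailing field, 2/6/6/14 nibbles depending on mode and precision) are
nibble-packed in word order; unmatched words are stored whole. The probe
length (50), window depth (15) and 8-bit primary field are fixed constants,
exposed read-only.

The encoder finds the nearest match with a last-seen-index map — equivalent
to scanning the window, O(1) per word — while the decoder reconstructs by
indexing its own history, so encoder and decoder window states coincide step
by step (asserted by co-simulation in the tests).

## Arithmetic coder

A static (non-adaptive) multi-symbol coder: frequencies are counted over the
exact stream and serialized with it (1 byte alphabet size + one u16 per
symbol), so unseen symbols cannot arise at decode time and no escape
mechanism exists. Totals above 2^16 are scaled down proportionally with
observed symbols floored at count 1; individual stored counts are clamped to
65535 to fit the u16 field (relevant only to single-symbol streams — the
coder's own integer arithmetic tolerates totals up to 2^24).

The bitstream is a byte-oriented range coder: 32-bit range, 64-bit low
accumulator with deferred-carry cache, renormalization when the range drops
below 2^24, 5-byte flush, and remainder absorption into the top symbol's
interval. Byte renormalization makes the decoder consume exactly the number
of bytes the encoder produced, so a truncated payload deterministically
raises rather than mis-decoding. The layout is frozen and guarded by a
golden-bytes test; measured overhead at n = 10⁴ uniform 16-ary symbols is
about 4 bytes over the Shannon bound n·H.

## Container and archive

Extraction is lexical: the byte stream is scanned for `<peaks ...>` /
`</peaks>` spans and only the text span is lifted; `<peaksCount>` and
self-closing `<peaks/>` are recognized and left alone. Attribute values
(`precision`, `byteOrder`, `compressionType`) are read from the open tag.
The skeleton (all non-payload bytes, verbatim) is serialized as alternating
literal runs and placeholders and gzipped as one member. Each scan record is
either coded (pad bytes + m/z block + intensity block) or raw; a coded
record that fails to beat plain DEFLATE of the payload text is replaced by
the raw record, so per-scan table overhead can never inflate tiny scans.
Archive layout: magic `MZC1`, version byte, length-prefixed gzipped
skeleton, record count, records. `split_archive`/`join_archive` (CLI
`--two-files`) expose the metadata and pair sections as two files.

## Synthetic data generator

Fixtures emulate exactly the two statistics the codecs exploit. m/z series:
a uniform start in 100–600 Th plus cumulative positive log-normal increments
— mean step 0.002 Th for profile-like scans (dense axis sampling), 0.7 Th
for centroid-like (gaps between picked peaks), log-sigma 0.3 ("noise").
Scan sizes: 20–800 pairs (centroid) or 6000–12000 (profile). Intensities:
log-uniform over 10⁴–10⁶, i.e. a bounded dynamic range spanning a handful of
exponent bytes with effectively random mantissas. Same spec + seed yields
identical bytes.

Not modeled: isotope envelopes, charge states, peak shapes, MS² structure,
rich scan metadata, vendor pretty-printing. Passing tests therefore
demonstrate correctness on arbitrary bit patterns and effectiveness on data
with the assumed smoothness/range structure; absolute ratios on real
repository files will differ with instrument, mode and metadata share.

## Numerical and degenerate-input choices

Empty files, files without peaks elements, empty payloads, odd word counts,
zero-pair scans, `byteOrder` ≠ network and pre-compressed payloads all have
defined paths (coded-degenerate or raw) and round-trip exactly. The empty
symbol stream encodes to zero bytes. Mode ties break to B; empty scans
default to mode A. All multi-byte integers in the archive are big-endian.

## Problem sizes

The test suite and acceptance script run on synthetic files of 1–4 scans
with up to ~12,000 pairs per profile scan (hundreds of kilobytes of pairs
per measurement), 100+ fixtures in the round-trip sweep, and n = 10⁴ symbols
for coder-efficiency measurements — sizes chosen so the whole suite and the
acceptance run each finish in seconds on one CPU while exercising every code
path at realistic per-scan scale.

## Known limitations

* mzML input is out of scope (its pair payloads are equivalent; conversion
  tools exist).
* No random access into individual scans of an archive (the per-scan
  independence needed for it is already in place).
* No timing/memory benchmarking beyond what the bench report prints.
* The raw-fallback decision is size-greedy per scan; a global optimizer
  could in principle do marginally better.
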