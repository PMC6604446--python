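"""m/z codec: digitwise deltas, run coding, byte-exact inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masscomp.errors import CorruptBlockError
from masscomp.ieee_words import Precision, word_to_hex
from masscomp.mz_codec import (
    decode_mz_scan,
    deserialize_mz_block,
    encode_mz_scan,
    hex_add,
    hex_delta,
    pack_nibbles,
    serialize_mz_block,
    unpack_nibbles,
)


class TestDigitDelta:
    def test_smooth_neighbors_share_prefix(self):
        d = hex_delta("41FBC000", "41FBC800")
        assert d.front == 5
        assert d.core == "800"
        assert hex_add("41FBC000", d) == "41FBC800"

    def test_identical_values(self):
        d = hex_delta("DEADBEEF", "DEADBEEF")
        assert d.front == 8 and d.core == ""

    def test_wraparound_no_borrow(self):
        """(2-8) mod 16 = A in the last digit; no borrow into earlier digits."""
        d = hex_delta("00000008", "00000002")
        assert d.front == 7 and d.core == "A"
        assert hex_add("00000008", d) == "00000002"

    def test_back_run_tracked_for_double(self):
        d = hex_delta("0" * 16, "00A5000000000000", track_back=True)
        assert d.front == 2 and d.back == 12 and d.core == "A5"

    def test_all_zero_delta_has_zero_back(self):
        d = hex_delta("FF", "FF", track_back=True)
        assert d.front == 2 and d.back == 0

    def test_exhaustive_two_digit_inversion(self):
        """hex_add inverts hex_delta on all 2-digit prev x cur pairs."""
        digits = [format(v, "02X") for v in range(256)]
        for prev in digits:
            for cur in digits:
                assert hex_add(prev, hex_delta(prev, cur)) == cur

    def test_front_equals_shared_prefix(self, rng):
        """The mod-16 delta's front run equals the shared hex prefix length."""
        for _ in range(200):
            a, b = (int(x) for x in rng.integers(0, 2**32, 2))
            ha, hb = word_to_hex(a, Precision.SINGLE), word_to_hex(b, Precision.SINGLE)
            shared = 0
            while shared < 8 and ha[shared] == hb[shared]:
                shared += 1
            d = hex_delta(ha, hb)
            if shared < 8 and (int(hb[shared], 16) - int(ha[shared], 16)) % 16 != 0:
                assert d.front == shared


class TestNibblePacking:
    @pytest.mark.parametrize("n", [0, 1, 2, 7, 64])
    def test_roundtrip(self, n, rng):
        digits = rng.integers(0, 16, n).astype(np.uint8)
        assert np.array_equal(unpack_nibbles(pack_nibbles(digits), n), digits)


class TestScanRoundTrip:
    @pytest.mark.parametrize("precision", list(Precision))
    def test_random_streams(self, precision, rng):
        for n in (0, 1, 2, 17, 500):
            words = rng.integers(0, 2**63, n, dtype=np.uint64)
            if precision is Precision.SINGLE:
                words = words & np.uint64(0xFFFFFFFF)
            block = encode_mz_scan(words, precision)
            assert np.array_equal(decode_mz_scan(block, precision), words)

    @pytest.mark.parametrize("precision", list(Precision))
    def test_serialized_roundtrip(self, precision, rng):
        words = rng.integers(0, 2**32, 300, dtype=np.uint64)
        blob = serialize_mz_block(encode_mz_scan(words, precision))
        block = deserialize_mz_block(blob, precision)
        assert np.array_equal(decode_mz_scan(block, precision), words)

    def test_constant_stream_compresses(self):
        words = np.full(1000, 0x41FBC123, dtype=np.uint64)
        block = encode_mz_scan(words, Precision.SINGLE)
        assert not block.raw_fallback
        # only the first value contributes core digits; the other 999 deltas
        # are all-zero (front == 8)
        assert block.n_core_digits == 8
        assert block.front.decode() == [0] + [8] * 999
        blob = serialize_mz_block(block)
        assert len(blob) < 100 < 4000  # far below the raw 4000 bytes
        assert np.array_equal(decode_mz_scan(block, Precision.SINGLE), words)

    def test_integer_ramp(self):
        """w, w+1, w+2 ... leaves a single trailing core digit per delta."""
        base = 0x41FBC100
        words = np.arange(base, base + 16, dtype=np.uint64)
        block = encode_mz_scan(words, Precision.SINGLE)
        fronts = block.front.decode()
        # within one nibble period every +1 touches only the last digit
        assert fronts[1:] == [7] * 15
        assert np.array_equal(decode_mz_scan(block, Precision.SINGLE), words)
        # past the nibble wrap a carry touches two digits but inversion holds
        long_ramp = np.arange(base, base + 500, dtype=np.uint64)
        block = encode_mz_scan(long_ramp, Precision.SINGLE)
        assert set(block.front.decode()[1:]) <= {5, 6, 7}
        assert np.array_equal(decode_mz_scan(block, Precision.SINGLE), long_ramp)

    def test_adversarial_wraparound(self):
        words = np.array([0xFFFFFFFF, 0x00000000, 0xFFFFFFFF, 0x80000000],
                         dtype=np.uint64)
        block = encode_mz_scan(words, Precision.SINGLE)
        assert np.array_equal(decode_mz_scan(block, Precision.SINGLE), words)

    @settings(derandomize=True, max_examples=60)
    @given(vals=st.lists(st.integers(0, 2**64 - 1), max_size=60))
    def test_property_roundtrip_double(self, vals):
        words = np.array(vals, dtype=np.uint64)
        block = encode_mz_scan(words, Precision.DOUBLE)
        assert np.array_equal(decode_mz_scan(block, Precision.DOUBLE), words)

    def test_tiny_scan_raw_fallback_still_exact(self, rng):
        words = rng.integers(0, 2**32, 2, dtype=np.uint64)
        block = encode_mz_scan(words, Precision.SINGLE)
        assert block.raw_fallback  # per-scan tables would dwarf 8 bytes
        blob = serialize_mz_block(block)
        restored = deserialize_mz_block(blob, Precision.SINGLE)
        assert np.array_equal(decode_mz_scan(restored, Precision.SINGLE), words)


class TestEffectiveness:
    @pytest.mark.parametrize("precision,dtype", [
        (Precision.SINGLE, np.dtype(">f4")),
        (Precision.DOUBLE, np.dtype(">f8")),
    ])
    def test_smooth_monotone_beats_raw(self, precision, dtype, rng):
        mz = 400.0 + np.cumsum(np.exp(rng.normal(np.log(0.002), 0.3, 5000)))
        words = np.frombuffer(mz.astype(dtype).tobytes(),
                              dtype=dtype.str.replace("f", "u")).astype(np.uint64)
        block = encode_mz_scan(words, precision)
        assert not block.raw_fallback
        coded = len(serialize_mz_block(block))
        assert coded < len(words) * precision.n_bytes


class TestCorruption:
    def test_inconsistent_core_count(self, rng):
        words = rng.integers(0, 2**32, 100, dtype=np.uint64)
        blob = bytearray(serialize_mz_block(encode_mz_scan(words, Precision.SINGLE)))
        with pytest.raises(CorruptBlockError):
            deserialize_mz_block(bytes(blob[:-3]), Precision.SINGLE)
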