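"""Intensity codec: mode probing, windowed matching, byte-exact inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from masscomp.errors import CorruptBlockError
from masscomp.ieee_words import Precision
from masscomp.intensity_codec import (
    WINDOW_SIZE,
    IntensityScanBlock,
    MatchMode,
    decode_intensity_scan,
    deserialize_intensity_block,
    encode_intensity_scan,
    find_match,
    select_mode,
    serialize_intensity_block,
)


class TestMatchModeGeometry:
    @pytest.mark.parametrize("mode,precision,nibbles", [
        (MatchMode.A, Precision.SINGLE, 6),
        (MatchMode.B, Precision.SINGLE, 2),
        (MatchMode.A, Precision.DOUBLE, 14),
        (MatchMode.B, Precision.DOUBLE, 6),
    ])
    def test_residual_widths(self, mode, precision, nibbles):
        assert mode.residual_nibbles(precision) == nibbles
        matched = 8 + mode.tail_bits(precision)
        assert matched + nibbles * 4 == precision.width


class TestFindMatch:
    def test_immediate_previous(self):
        w = 0x42AA1234
        prev = 0x42BB9999  # same first byte
        assert find_match([prev], w, MatchMode.A, Precision.SINGLE) == 1

    def test_empty_window(self):
        assert find_match([], 0x42AA1234, MatchMode.A, Precision.SINGLE) == 0

    def test_nearest_wins(self):
        w = 0x42000000
        window = [0x41000000, 0x42FFFFFF, 0x42123456]  # matches at 2 and 3
        assert find_match(window, w, MatchMode.A, Precision.SINGLE) == 2

    def test_eviction_beyond_window(self):
        """A match 16 steps back has just been evicted: pointer must be 0."""
        target = 0x42AA0000
        fillers = [(0x50 + i) << 24 for i in range(WINDOW_SIZE)]  # distinct bytes
        window = fillers + [target]  # target now at distance 16
        assert find_match(window, target, MatchMode.A, Precision.SINGLE) == 0

    def test_mode_b_requires_tail_match(self):
        w = 0x42AA1234
        near = 0x42BB9999  # head matches, tail differs
        far = 0x42001234   # head and last-16 match
        assert find_match([near, far], w, MatchMode.B, Precision.SINGLE) == 2


class TestModeSelection:
    def test_shared_head_and_tail_prefers_b(self):
        words = [0x42000000 | (i << 16) for i in range(50)]  # same head, same last 16
        assert select_mode(words, Precision.SINGLE) is MatchMode.B

    def test_shared_head_only_prefers_a(self):
        rng = np.random.default_rng(1)
        words = [0x42000000 | int(x) for x in rng.integers(0, 2**24, 50)]
        assert select_mode(words, Precision.SINGLE) is MatchMode.A

    def test_empty_defaults_to_a(self):
        assert select_mode([], Precision.SINGLE) is MatchMode.A

    def test_tie_breaks_to_b(self):
        words = [0x42001234] * 50  # every bit shared: both modes match 49
        assert select_mode(words, Precision.SINGLE) is MatchMode.B


class TestScanRoundTrip:
    def test_constant_stream(self):
        words = np.full(1000, 0x42AA1234, dtype=np.uint64)
        block = encode_intensity_scan(words, Precision.SINGLE)
        assert not block.raw_fallback
        pointers = block.pointers.decode()
        assert pointers == [0] + [1] * 999
        assert len(block.unmatched) == 4  # exactly one stored word
        assert np.array_equal(decode_intensity_scan(block, Precision.SINGLE), words)

    def test_alternating_pair_matches_at_distance_two(self):
        x, y = 0x42AA1234, 0x51BB9876  # share nothing
        words = np.array([x, y] * 20, dtype=np.uint64)
        block = encode_intensity_scan(words, Precision.SINGLE)
        assert block.pointers.decode() == [0, 0] + [2] * 38
        assert np.array_equal(decode_intensity_scan(block, Precision.SINGLE), words)

    def test_all_distinct_heads_fall_back_to_raw(self):
        """With no matches, pointers are pure overhead; raw fallback triggers."""
        words = np.array([(i << 24) | 0x00A5C3 for i in range(200)],
                         dtype=np.uint64)  # 200 distinct first bytes
        block = encode_intensity_scan(words, Precision.SINGLE)
        assert block.raw_fallback
        assert np.array_equal(decode_intensity_scan(block, Precision.SINGLE), words)

    @pytest.mark.parametrize("precision", list(Precision))
    def test_random_streams(self, precision, rng):
        for n in (0, 1, 2, 49, 51, 700):
            words = rng.integers(0, 2**63, n, dtype=np.uint64)
            if precision is Precision.SINGLE:
                words = words & np.uint64(0xFFFFFFFF)
            block = encode_intensity_scan(words, precision)
            assert np.array_equal(decode_intensity_scan(block, precision), words)

    @pytest.mark.parametrize("precision", list(Precision))
    def test_mode_flipping_streams(self, precision, rng):
        """Streams engineered so the probe picks each mode in turn."""
        shift = precision.width - 8
        tail_bits = MatchMode.B.tail_bits(precision)
        # mode B friendly: fixed head, fixed tail, random middle
        mid_bits = precision.width - 8 - tail_bits
        mids = rng.integers(0, 2**mid_bits, 300, dtype=np.uint64)
        b_words = (np.uint64(0x42) << np.uint64(shift)) | (mids << np.uint64(tail_bits)) | np.uint64(0x77)
        # mode A friendly: fixed head, everything else random
        rest = rng.integers(0, 2**shift, 300, dtype=np.uint64)
        a_words = (np.uint64(0x42) << np.uint64(shift)) | rest
        for words, want in ((b_words, MatchMode.B), (a_words, MatchMode.A)):
            block = encode_intensity_scan(words, precision)
            assert block.mode is want
            assert np.array_equal(decode_intensity_scan(block, precision), words)

    @pytest.mark.parametrize("precision", list(Precision))
    def test_serialized_roundtrip(self, precision, rng):
        words = rng.integers(0, 2**32, 400, dtype=np.uint64)
        blob = serialize_intensity_block(encode_intensity_scan(words, precision))
        block = deserialize_intensity_block(blob, precision)
        assert np.array_equal(decode_intensity_scan(block, precision), words)

    @settings(derandomize=True, max_examples=60)
    @given(vals=st.lists(st.integers(0, 2**32 - 1), max_size=80))
    def test_property_roundtrip(self, vals):
        words = np.array(vals, dtype=np.uint64)
        block = encode_intensity_scan(words, Precision.SINGLE)
        assert np.array_equal(decode_intensity_scan(block, Precision.SINGLE), words)


class TestEffectiveness:
    def test_bounded_exponent_matches_over_90_percent(self, rng):
        """Range-limited intensities share exponent bytes: high match rate."""
        vals = np.exp(rng.uniform(np.log(1e4), np.log(1e6), 5000))
        words = np.frombuffer(vals.astype(">f4").tobytes(), dtype=">u4").astype(np.uint64)
        block = encode_intensity_scan(words, Precision.SINGLE)
        assert not block.raw_fallback
        pointers = block.pointers.decode()
        match_rate = sum(1 for p in pointers if p) / len(pointers)
        assert match_rate > 0.90
        coded = len(serialize_intensity_block(block))
        assert coded < len(words) * 4


class TestCorruption:
    def test_truncated_block_raises(self, rng):
        vals = np.exp(rng.uniform(np.log(1e4), np.log(1e6), 300))
        words = np.frombuffer(vals.astype(">f4").tobytes(), dtype=">u4").astype(np.uint64)
        blob = serialize_intensity_block(encode_intensity_scan(words, Precision.SINGLE))
        with pytest.raises(CorruptBlockError):
            deserialize_intensity_block(blob[:-5], Precision.SINGLE)

    def test_pointer_beyond_history_raises(self):
        from masscomp.range_coder import CodedStream
        block = IntensityScanBlock(
            n_values=1, precision=Precision.SINGLE, mode=MatchMode.A,
            raw_fallback=False,
            pointers=CodedStream.from_symbols([3], 16),
            residuals=b"\x00\x00\x00", n_residual_nibbles=6, unmatched=b"",
        )
        with pytest.raises(CorruptBlockError):
            decode_intensity_scan(block, Precision.SINGLE)
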