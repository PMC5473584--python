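"""Unit and property tests for the primitive transforms.

Expected values for the non-trivial cases are computed by independent
oracles (exact decimal/rational arithmetic, naive prefix sums, explicit
group-sum decoding) rather than by the code under test.
"""

import decimal
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mmtfkit import codec_core as cc

# ---------------------------------------------------------------------------
# oracles


def round_half_away_decimal(value: float, divisor: int) -> int:
    """Exact-arithmetic oracle for fixed-point rounding (half away from 0).

    Operates on the value's shortest decimal representation — the digits
    a person (or a structure file) wrote — so ``1.0005`` scales to the
    exact decimal 1000.5; ROUND_HALF_UP on the magnitude is half-away.
    """
    scaled = decimal.Decimal(repr(value)) * divisor
    magnitude = abs(scaled).to_integral_value(rounding=decimal.ROUND_HALF_UP)
    return int(magnitude if scaled >= 0 else -magnitude)


def naive_prefix_sum(deltas):
    out = []
    acc = 0
    for d in deltas:
        acc += d
        out.append(acc)
    return out


def brute_force_recursive_decode(stream, lo=-32768, hi=32767):
    """Explicit group-sum oracle: split into boundary-runs + terminator."""
    out = []
    group = []
    for v in stream:
        group.append(v)
        if v != lo and v != hi:
            out.append(sum(group))
            group = []
    assert not group, "truncated stream"
    return out


# ---------------------------------------------------------------------------
# integer (fixed-point) encoding


class TestIntegerEncode:
    def test_coordinate_times_1000(self):
        assert cc.integer_encode([1.000], 1000).tolist() == [1000]

    def test_zero(self):
        assert cc.integer_encode([0.0], 1000).tolist() == [0]

    def test_half_rounds_away_from_zero(self):
        # oracle: exact decimal arithmetic on the stored double
        expected = round_half_away_decimal(1.0005, 1000)
        assert expected == 1001
        assert cc.integer_encode([1.0005], 1000).tolist() == [expected]

    def test_negative_half_rounds_away(self):
        expected = round_half_away_decimal(-1.0005, 1000)
        assert expected == -1001
        assert cc.integer_encode([-1.0005], 1000).tolist() == [expected]

    def test_overflow_names_index(self):
        with pytest.raises(cc.RangeError, match="index 1"):
            cc.integer_encode([0.0, 3.0e6], 1000)

    def test_bad_divisor(self):
        with pytest.raises(ValueError):
            cc.integer_encode([1.0], 0)

    @given(
        st.lists(st.integers(min_value=-(10**6), max_value=10**6), max_size=50),
        st.sampled_from([1, 10, 100, 1000]),
    )
    def test_grid_inputs_are_lossless(self, ints, divisor):
        reals = [i / divisor for i in ints]
        encoded = cc.integer_encode(reals, divisor)
        assert cc.integer_decode(encoded, divisor).tolist() == pytest.approx(reals)
        assert encoded.tolist() == ints

    @given(
        st.lists(st.floats(min_value=-1e4, max_value=1e4, allow_nan=False), max_size=50),
        st.sampled_from([10, 100, 1000]),
    )
    def test_half_quantum_bound(self, reals, divisor):
        decoded = cc.integer_decode(cc.integer_encode(reals, divisor), divisor)
        err = np.abs(np.asarray(reals) - decoded)
        assert np.all(err <= 0.5 / divisor + 1e-12)


class TestIntegerDecode:
    def test_inverse_of_coordinate_example(self):
        assert cc.integer_decode([1000], 1000).tolist() == [1.0]

    def test_occupancy_times_100(self):
        assert cc.integer_decode([100], 100).tolist() == [1.0]

    def test_exact_rational_division(self):
        expected = float(Fraction(-12345, 1000))
        assert cc.integer_decode([-12345], 1000).tolist() == [expected] == [-12.345]


# ---------------------------------------------------------------------------
# delta


class TestDelta:
    def test_small_example(self):
        assert cc.delta_encode([1000, 1003, 1005]).tolist() == [1000, 3, 2]

    def test_singleton(self):
        assert cc.delta_encode([5]).tolist() == [5]

    def test_serial_numbers_become_ones(self):
        out = cc.delta_encode(list(range(1, 2001)))
        assert out.tolist() == [1] * 2000

    def test_decode_inverse(self):
        assert cc.delta_decode([1000, 3, 2]).tolist() == [1000, 1003, 1005]

    def test_empty(self):
        assert cc.delta_decode([]).tolist() == []
        assert cc.delta_encode([]).tolist() == []

    def test_difference_overflow(self):
        with pytest.raises(cc.RangeError):
            cc.delta_encode([-(2**31) + 1, 2**31 - 1])

    @given(st.lists(st.integers(min_value=-(10**6), max_value=10**6), max_size=100))
    def test_round_trip_matches_prefix_sum_oracle(self, ints):
        deltas = cc.delta_encode(ints)
        assert cc.delta_decode(deltas).tolist() == ints
        assert naive_prefix_sum(deltas.tolist()) == ints

    @given(st.lists(st.integers(min_value=-(10**4), max_value=10**4), min_size=1, max_size=100))
    def test_last_element_equals_sum_of_deltas(self, ints):
        deltas = cc.delta_encode(ints)
        assert cc.delta_decode(deltas)[-1] == sum(deltas.tolist())


# ---------------------------------------------------------------------------
# run length


class TestRunLength:
    def test_constant_occupancy_run(self):
        assert cc.rle_encode([100] * 2000).tolist() == [100, 2000]

    def test_empty(self):
        assert cc.rle_encode([]).tolist() == []
        assert cc.rle_decode([]).tolist() == []

    def test_two_runs(self):
        assert cc.rle_encode([1, 1, 2]).tolist() == [1, 2, 2, 1]

    def test_decode_expansion(self):
        assert cc.rle_decode([1, 2000]).tolist() == [1] * 2000

    def test_decode_single(self):
        assert cc.rle_decode([7, 1]).tolist() == [7]

    def test_odd_length_rejected(self):
        with pytest.raises(cc.FormatError, match="odd"):
            cc.rle_decode([1, 2, 3])

    def test_nonpositive_count_rejected(self):
        with pytest.raises(cc.FormatError, match="count"):
            cc.rle_decode([1, 0])

    @given(st.lists(st.integers(min_value=-5, max_value=5), max_size=200))
    def test_round_trip_and_invariants(self, ints):
        pairs = cc.rle_encode(ints)
        assert cc.rle_decode(pairs).tolist() == ints
        counts = pairs.tolist()[1::2]
        values = pairs.tolist()[0::2]
        assert sum(counts) == len(ints)
        assert all(c >= 1 for c in counts)
        # maximal runs: no two adjacent pairs share a value
        assert all(values[i] != values[i + 1] for i in range(len(values) - 1))


# ---------------------------------------------------------------------------
# recursive indexing


class TestRecursiveIndex:
    def test_decomposes_out_of_range_value(self):
        assert cc.recursive_index_encode([32867]).tolist() == [32767, 100]

    def test_in_range_verbatim(self):
        assert cc.recursive_index_encode([100]).tolist() == [100]

    def test_boundary_value_gets_zero_terminator(self):
        out = cc.recursive_index_encode([32767])
        assert out.tolist() == [32767, 0]
        assert brute_force_recursive_decode(out.tolist()) == [32767]

    def test_negative_saturation(self):
        out = cc.recursive_index_encode([-40000])
        assert out.tolist() == [-32768, -7232]
        assert brute_force_recursive_decode(out.tolist()) == [-40000]

    def test_decode_sums_components(self):
        assert cc.recursive_index_decode([32767, 100]).tolist() == [32867]

    def test_decode_in_range_passthrough(self):
        assert cc.recursive_index_decode([5, -3]).tolist() == [5, -3]

    def test_truncated_stream_rejected(self):
        with pytest.raises(cc.FormatError, match="truncated"):
            cc.recursive_index_decode([32767])
        with pytest.raises(cc.FormatError, match="truncated"):
            cc.recursive_index_decode([100, -32768])

    def test_output_dtype_is_int16(self):
        assert cc.recursive_index_encode([1]).dtype == np.int16

    def test_dense_grid_round_trip_against_oracle(self):
        grid = np.concatenate(
            [
                np.arange(-(10**6), 10**6, 4093),
                [-(10**6), 10**6, -32769, -32768, -32767, 32766, 32767, 32768, 0],
            ]
        )
        encoded = cc.recursive_index_encode(grid)
        assert cc.recursive_index_decode(encoded).tolist() == grid.tolist()
        assert brute_force_recursive_decode(encoded.tolist()) == grid.tolist()

    @given(st.lists(st.integers(min_value=-(2**20), max_value=2**20), max_size=50))
    def test_round_trip_and_invariants(self, ints):
        encoded = cc.recursive_index_encode(ints)
        assert encoded.dtype == np.int16
        stream = encoded.tolist()
        assert all(-32768 <= v <= 32767 for v in stream)
        assert cc.recursive_index_decode(encoded).tolist() == ints
        assert brute_force_recursive_decode(stream) == ints

    @given(st.lists(st.integers(min_value=-(2**15), max_value=2**15), max_size=50))
    def test_8bit_variant_round_trips(self, ints):
        encoded = cc.recursive_index_encode(ints, bits=8)
        assert encoded.dtype == np.int8
        assert cc.recursive_index_decode(encoded, bits=8).tolist() == ints
        assert brute_force_recursive_decode(encoded.tolist(), -128, 127) == ints
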