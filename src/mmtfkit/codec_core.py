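"""Primitive columnar encoding transforms and their exact inverses.

The transforms here are pure array-to-array functions: fixed-point integer
encoding, delta encoding, run-length encoding and recursive indexing.
Byte-level packing and codec composition live in :mod:`mmtfkit.codec_registry`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "CodecError",
    "RangeError",
    "FormatError",
    "integer_encode",
    "integer_decode",
    "delta_encode",
    "delta_decode",
    "rle_encode",
    "rle_decode",
    "recursive_index_encode",
    "recursive_index_decode",
]

INT32_MIN = -(2**31)
INT32_MAX = 2**31 - 1

#: (lower boundary, upper boundary) of the recursive-indexing targets.
RECURSIVE_BOUNDS = {16: (-32768, 32767), 8: (-128, 127)}


class CodecError(Exception):
    """Base class for codec failures."""


class RangeError(CodecError):
    """A value does not fit the target integer range."""


class FormatError(CodecError):
    """Encoded data is structurally invalid (truncated, malformed)."""


def _as_int32(values: Sequence[int], name: str = "input") -> np.ndarray:
    arr = np.asarray(values, dtype=np.int64)
    if arr.ndim != 1:
        arr = arr.reshape(-1)
    bad = np.flatnonzero((arr < INT32_MIN) | (arr > INT32_MAX))
    if bad.size:
        raise RangeError(
            f"{name}[{bad[0]}] = {arr[bad[0]]} outside signed 32-bit range"
        )
    return arr.astype(np.int32)


def integer_encode(reals: Sequence[float], divisor: int) -> np.ndarray:
    """Fixed-point encode real values as 32-bit integers.

    Each value is multiplied by ``divisor`` and rounded to the nearest
    integer, with exact halves rounded away from zero.

    Parameters
    ----------
    reals
        Column of real numbers.
    divisor
        Positive fixed-point scale factor (1000 keeps 3 decimals, 100
        keeps 2, 10 keeps 1).

    Returns
    -------
    numpy.ndarray of int32

    Raises
    ------
    RangeError
        If a scaled value overflows the signed 32-bit range.
    """
    if divisor < 1:
        raise ValueError(f"divisor must be >= 1, got {divisor}")
    arr = np.asarray(reals, dtype=np.float64).reshape(-1)
    scaled = arr * divisor
    # round half away from zero
    rounded = np.where(scaled >= 0, np.floor(scaled + 0.5), np.ceil(scaled - 0.5))
    bad = np.flatnonzero((rounded < INT32_MIN) | (rounded > INT32_MAX))
    if bad.size:
        raise RangeError(
            f"value at index {bad[0]} ({arr[bad[0]]!r} x {divisor}) overflows int32"
        )
    return rounded.astype(np.int32)


def integer_decode(ints: Sequence[int], divisor: int) -> np.ndarray:
    """Inverse of :func:`integer_encode`: divide by the fixed-point divisor."""
    if divisor < 1:
        raise ValueError(f"divisor must be >= 1, got {divisor}")
    arr = np.asarray(ints, dtype=np.int64).reshape(-1)
    return arr / float(divisor)


def delta_encode(ints: Sequence[int]) -> np.ndarray:
    """Store the first value followed by successive differences."""
    arr = _as_int32(ints).astype(np.int64)
    if arr.size == 0:
        return arr.astype(np.int32)
    out = np.empty_like(arr)
    out[0] = arr[0]
    np.subtract(arr[1:], arr[:-1], out=out[1:])
    return _as_int32(out, "delta")


def delta_decode(deltas: Sequence[int]) -> np.ndarray:
    """Prefix-sum inverse of :func:`delta_encode`."""
    arr = _as_int32(deltas, "deltas").astype(np.int64)
    out = np.cumsum(arr)
    return _as_int32(out, "cumulative sum")


def rle_encode(ints: Sequence[int]) -> np.ndarray:
    """Run-length encode into a flat (value, count, value, count, ...) array.

    Runs are maximal, so adjacent pairs always carry distinct values.
    """
    arr = _as_int32(ints)
    if arr.size == 0:
        return arr
    starts = np.concatenate(([0], np.flatnonzero(arr[1:] != arr[:-1]) + 1))
    counts = np.diff(np.concatenate((starts, [arr.size])))
    out = np.empty(2 * starts.size, dtype=np.int64)
    out[0::2] = arr[starts]
    out[1::2] = counts
    return _as_int32(out, "rle")


def rle_decode(pairs: Sequence[int]) -> np.ndarray:
    """Expand flat (value, count) pairs back to the full column."""
    arr = np.asarray(pairs, dtype=np.int64).reshape(-1)
    if arr.size % 2 != 0:
        raise FormatError(f"run-length data has odd length {arr.size}")
    values = arr[0::2]
    counts = arr[1::2]
    if np.any(counts < 1):
        i = int(np.flatnonzero(counts < 1)[0])
        raise FormatError(f"run-length pair {i} has non-positive count {counts[i]}")
    return _as_int32(np.repeat(values, counts), "rle expansion")


def recursive_index_encode(ints: Sequence[int], bits: int = 16) -> np.ndarray:
    """Decompose 32-bit integers into a narrower signed integer stream.

    A value outside the target range is emitted as a run of saturated
    boundary values followed by the remainder; the run components sum to
    the original value.  A value equal to an exact multiple of a boundary
    is closed with an explicit 0 so the decoder always sees a
    non-boundary terminator.  In-range values are emitted verbatim.

    Parameters
    ----------
    ints
        Column of signed 32-bit integers.
    bits
        Target width, 16 (default) or 8.
    """
    lo, hi = RECURSIVE_BOUNDS[bits]
    arr = _as_int32(ints)
    out: list[int] = []
    for v in arr.tolist():
        if lo < v < hi:
            out.append(v)
            continue
        if v >= 0:
            while v >= hi:
                out.append(hi)
                v -= hi
        else:
            while v <= lo:
                out.append(lo)
                v -= lo
        out.append(v)
    return np.asarray(out, dtype=np.int16 if bits == 16 else np.int8)


def recursive_index_decode(small: Sequence[int], bits: int = 16) -> np.ndarray:
    """Re-accumulate a recursive-index stream into 32-bit integers.

    Scans left to right summing while the current element is a boundary
    value; the first non-boundary element closes the group.
    """
    lo, hi = RECURSIVE_BOUNDS[bits]
    arr = np.asarray(small, dtype=np.int64).reshape(-1)
    bad = np.flatnonzero((arr < lo) | (arr > hi))
    if bad.size:
        raise FormatError(
            f"element {bad[0]} = {arr[bad[0]]} outside the {bits}-bit range"
        )
    out: list[int] = []
    acc = 0
    open_group = False
    for v in arr.tolist():
        acc += v
        if v == hi or v == lo:
            open_group = True
            continue
        out.append(acc)
        acc = 0
        open_group = False
    if open_group:
        raise FormatError("truncated recursive-index stream: group not terminated")
    return _as_int32(out, "recursive sum")
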