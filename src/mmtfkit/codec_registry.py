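"""Codec table and byte-exact packing of encoded records.

An encoded record is a 12-byte big-endian header — codec type, number of
decoded values, codec parameter — followed by a big-endian payload.  Each
codec type names a fixed composition of :mod:`mmtfkit.codec_core`
primitives; the table below follows the published format specification
v1.0 so records interoperate with archive-produced files.

=====  ==========================================================
type   strategy
=====  ==========================================================
1      pass-through, 32-bit float
2      pass-through, 8-bit int
3      pass-through, 16-bit int
4      pass-through, 32-bit int
5      fixed-width strings (parameter = byte width)
6      run-length encoded 8-bit characters
7      run-length encoded 32-bit ints
8      delta + run-length encoded 32-bit ints
9      fixed-point (parameter = divisor) + run-length floats
10     fixed-point + delta + 16-bit recursive-index floats
11     fixed-point 32-bit floats
12     fixed-point + 16-bit recursive-index floats
13     fixed-point + 8-bit recursive-index floats
14     16-bit recursive-index ints
15     8-bit recursive-index ints
=====  ==========================================================
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from . import codec_core as cc
from .codec_core import CodecError, FormatError

__all__ = [
    "CodecHeader",
    "EncodedField",
    "UnknownCodecError",
    "pack_record",
    "unpack_record",
    "encode_column",
    "decode_column",
]

HEADER_STRUCT = struct.Struct(">iii")
HEADER_SIZE = HEADER_STRUCT.size  # 12 bytes, always


class UnknownCodecError(CodecError):
    """Codec type not present in the registry."""


@dataclass(frozen=True)
class CodecHeader:
    """The 12-byte record header: strategy id, decoded length, parameter."""

    codec_type: int
    data_length: int
    codec_parameter: int = 0

    def pack(self) -> bytes:
        return HEADER_STRUCT.pack(self.codec_type, self.data_length, self.codec_parameter)

    @classmethod
    def unpack(cls, data: bytes) -> "CodecHeader":
        if len(data) < HEADER_SIZE:
            raise FormatError(f"record truncated: {len(data)} bytes, header needs {HEADER_SIZE}")
        return cls(*HEADER_STRUCT.unpack_from(data))


@dataclass(frozen=True)
class EncodedField:
    header: CodecHeader
    payload: bytes

    def tobytes(self) -> bytes:
        return self.header.pack() + self.payload


def _pad_strings(values: Sequence[str], width: int) -> bytes:
    chunks = []
    for i, s in enumerate(values):
        raw = s.encode("utf-8")
        if len(raw) > width:
            raise cc.RangeError(f"string {i} ({s!r}) exceeds width {width}")
        chunks.append(raw.ljust(width, b"\x00"))
    return b"".join(chunks)


def _chars_to_codes(values: Sequence[str]) -> np.ndarray:
    codes = np.zeros(len(values), dtype=np.int32)
    for i, ch in enumerate(values):
        if ch in ("", "\x00", None):
            continue
        if len(ch) != 1 or ord(ch) > 127:
            raise cc.RangeError(f"char column element {i} ({ch!r}) is not a single ASCII char")
        codes[i] = ord(ch)
    return codes


def _codes_to_chars(codes: np.ndarray) -> list[str]:
    return ["" if c == 0 else chr(c) for c in codes.tolist()]


class _Codec:
    """One registered strategy: primitive pipeline plus wire dtype."""

    #: numpy dtype of the big-endian payload elements; None = raw bytes
    wire_dtype: Any = None
    kind = "int"  # int | float | char | string
    default_parameter = 0

    def __init__(self, codec_type: int):
        self.codec_type = codec_type

    # encode() returns the typed column ready for pack_record
    def encode(self, values, parameter):
        raise NotImplementedError

    def decode(self, column, length, parameter):
        raise NotImplementedError

    def element_bytes(self, parameter: int) -> int:
        return np.dtype(self.wire_dtype).itemsize


class _PassFloat32(_Codec):
    wire_dtype = ">f4"
    kind = "float"

    def encode(self, values, parameter):
        return np.asarray(values, dtype=np.float32)

    def decode(self, column, length, parameter):
        return np.asarray(column, dtype=np.float32)


class _PassInt(_Codec):
    def __init__(self, codec_type, dtype):
        super().__init__(codec_type)
        self.wire_dtype = dtype

    def encode(self, values, parameter):
        target = np.dtype(self.wire_dtype)
        arr = np.asarray(values, dtype=np.int64)
        info = np.iinfo(target.newbyteorder("="))
        bad = np.flatnonzero((arr < info.min) | (arr > info.max))
        if bad.size:
            raise cc.RangeError(f"element {bad[0]} = {arr[bad[0]]} overflows {target}")
        return arr.astype(target.newbyteorder("="))

    def decode(self, column, length, parameter):
        return np.asarray(column).astype(np.int32)


class _FixedString(_Codec):
    kind = "string"
    default_parameter = 4

    def encode(self, values, parameter):
        return _pad_strings(values, parameter)

    def decode(self, column, length, parameter):
        raw = bytes(column)
        return [
            raw[i * parameter : (i + 1) * parameter].rstrip(b"\x00").decode("utf-8")
            for i in range(length)
        ]

    def element_bytes(self, parameter: int) -> int:
        if parameter < 1:
            raise FormatError(f"string codec requires positive width, got {parameter}")
        return parameter


class _RunLengthChar(_Codec):
    wire_dtype = ">i4"
    kind = "char"

    def encode(self, values, parameter):
        return cc.rle_encode(_chars_to_codes(values))

    def decode(self, column, length, parameter):
        return _codes_to_chars(cc.rle_decode(column))


class _RunLengthInt(_Codec):
    wire_dtype = ">i4"

    def encode(self, values, parameter):
        return cc.rle_encode(values)

    def decode(self, column, length, parameter):
        return cc.rle_decode(column)


class _DeltaRunLengthInt(_Codec):
    wire_dtype = ">i4"

    def encode(self, values, parameter):
        return cc.rle_encode(cc.delta_encode(values))

    def decode(self, column, length, parameter):
        return cc.delta_decode(cc.rle_decode(column))


class _RunLengthFloat(_Codec):
    wire_dtype = ">i4"
    kind = "float"
    default_parameter = 100

    def encode(self, values, parameter):
        return cc.rle_encode(cc.integer_encode(values, parameter))

    def decode(self, column, length, parameter):
        return cc.integer_decode(cc.rle_decode(column), parameter)


class _DeltaRecursiveFloat(_Codec):
    wire_dtype = ">i2"
    kind = "float"
    default_parameter = 1000

    def encode(self, values, parameter):
        return cc.recursive_index_encode(cc.delta_encode(cc.integer_encode(values, parameter)))

    def decode(self, column, length, parameter):
        return cc.integer_decode(cc.delta_decode(cc.recursive_index_decode(column)), parameter)


class _FixedPointFloat(_Codec):
    wire_dtype = ">i4"
    kind = "float"
    default_parameter = 100

    def encode(self, values, parameter):
        return cc.integer_encode(values, parameter)

    def decode(self, column, length, parameter):
        return cc.integer_decode(np.asarray(column, dtype=np.int64), parameter)


class _RecursiveFloat(_Codec):
    kind = "float"
    default_parameter = 1000

    def __init__(self, codec_type, bits):
        super().__init__(codec_type)
        self.bits = bits
        self.wire_dtype = ">i2" if bits == 16 else ">i1"

    def encode(self, values, parameter):
        return cc.recursive_index_encode(cc.integer_encode(values, parameter), self.bits)

    def decode(self, column, length, parameter):
        return cc.integer_decode(cc.recursive_index_decode(column, self.bits), parameter)


class _RecursiveInt(_Codec):
    def __init__(self, codec_type, bits):
        super().__init__(codec_type)
        self.bits = bits
        self.wire_dtype = ">i2" if bits == 16 else ">i1"

    def encode(self, values, parameter):
        return cc.recursive_index_encode(values, self.bits)

    def decode(self, column, length, parameter):
        return cc.recursive_index_decode(column, self.bits)


CODECS: dict[int, _Codec] = {
    1: _PassFloat32(1),
    2: _PassInt(2, ">i1"),
    3: _PassInt(3, ">i2"),
    4: _PassInt(4, ">i4"),
    5: _FixedString(5),
    6: _RunLengthChar(6),
    7: _RunLengthInt(7),
    8: _DeltaRunLengthInt(8),
    9: _RunLengthFloat(9),
    10: _DeltaRecursiveFloat(10),
    11: _FixedPointFloat(11),
    12: _RecursiveFloat(12, 16),
    13: _RecursiveFloat(13, 8),
    14: _RecursiveInt(14, 16),
    15: _RecursiveInt(15, 8),
}


def _codec_for(codec_type: int) -> _Codec:
    try:
        return CODECS[codec_type]
    except KeyError:
        raise UnknownCodecError(f"unknown codec type {codec_type}") from None


def pack_record(header: CodecHeader, encoded_values) -> bytes:
    """Pack a header plus an already-encoded typed column into bytes.

    The payload is written big-endian; total length is always
    ``12 + element_width * element_count``.
    """
    codec = _codec_for(header.codec_type)
    if isinstance(encoded_values, (bytes, bytearray)):
        payload = bytes(encoded_values)
    else:
        arr = np.asarray(encoded_values)
        payload = arr.astype(codec.wire_dtype).tobytes()
    return header.pack() + payload


def unpack_record(data: bytes):
    """Split a record into its header and typed column (native byte order)."""
    header = CodecHeader.unpack(data)
    codec = _codec_for(header.codec_type)
    payload = data[HEADER_SIZE:]
    width = codec.element_bytes(header.codec_parameter or codec.default_parameter)
    if codec.kind == "string":
        expected = header.data_length * width
        if len(payload) != expected:
            raise FormatError(
                f"codec {header.codec_type}: payload is {len(payload)} bytes, expected {expected}"
            )
        return header, payload
    if len(payload) % np.dtype(codec.wire_dtype).itemsize:
        raise FormatError(
            f"codec {header.codec_type}: payload length {len(payload)} is not a "
            f"multiple of the {np.dtype(codec.wire_dtype).itemsize}-byte element width"
        )
    column = np.frombuffer(payload, dtype=codec.wire_dtype).astype(
        np.dtype(codec.wire_dtype).newbyteorder("=")
    )
    return header, column


def encode_column(values, codec_type: int, codec_parameter: int | None = None) -> bytes:
    """Encode a column with the named strategy and pack it into a record."""
    codec = _codec_for(codec_type)
    if codec_parameter is None:
        codec_parameter = codec.default_parameter
    encoded = codec.encode(values, codec_parameter)
    header = CodecHeader(codec_type, len(values), codec_parameter)
    return pack_record(header, encoded)


def decode_column(record: bytes):
    """Decode a packed record back to its column.

    Returns a numpy array for numeric codecs, a list of strings for the
    char/string codecs.  The decoded length is validated against the
    header's data-length field.
    """
    header, column = unpack_record(record)
    codec = _codec_for(header.codec_type)
    parameter = header.codec_parameter or codec.default_parameter
    decoded = codec.decode(column, header.data_length, parameter)
    if len(decoded) != header.data_length:
        raise FormatError(
            f"codec {header.codec_type}: decoded {len(decoded)} values, "
            f"header promised {header.data_length}"
        )
    return decoded
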