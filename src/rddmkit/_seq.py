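"""Byte-level DNA sequence helpers shared across modules.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is
``3 - code``. All genome/read arrays in the package use this encoding.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i

_DECODE_LUT = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string to a uint8 code array."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if codes.max(initial=0) > 3:
        bad = chr(raw[int(np.argmax(codes))])
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE_LUT[codes].tobytes().decode()


def decode_rows(matrix: np.ndarray) -> list[str]:
    """Decode each row of a 2-D code matrix to a string."""
    as_bytes = _DECODE_LUT[matrix].tobytes()
    n, width = matrix.shape
    return [as_bytes[i * width:(i + 1) * width].decode() for i in range(n)]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))
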