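"""Base-encoding helpers shared across the package.

Bases are stored as uint8 codes: A=0, C=1, G=2, T=3, N=4.  Complementation
is ``3 - code`` for the four canonical bases and leaves N unchanged, which
keeps strand conversion a single vectorised operation.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ALPHABET = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgtn"):
    _ENCODE[_b] = _i

_COMP = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a string over {A,C,G,T,N} (case-insensitive) to uint8 codes.

    Any other character maps to N.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    return _ALPHABET[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))
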