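"""Small shared nucleotide-sequence helpers (encoding, revcomp, hamming)."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
# A,C,G,T -> 0..3; N -> 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN as uint8 0..4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))
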