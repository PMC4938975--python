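"""Low-level DNA sequence encoding helpers.

Bases are encoded A=0, C=1, G=2, T=3 so that the complement of code ``b``
is ``3 - b``. Any other symbol (N, ambiguity codes, gaps) maps to the
sentinel ``INVALID`` and is handled explicitly by callers.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
INVALID = np.uint8(255)

_CODE = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (invalid symbols -> 255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def encode_batch(seqs) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    joined = "".join(seqs)
    raw = np.frombuffer(joined.encode("ascii"), dtype=np.uint8)
    return _CODE[raw].reshape(len(seqs), lengths.pop())


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid codes only."""
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.size and codes.max() > 3:
        raise ValueError("cannot decode invalid base codes")
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def is_valid_dna(seq: str) -> bool:
    return bool(seq) and not np.any(encode(seq) == INVALID)
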