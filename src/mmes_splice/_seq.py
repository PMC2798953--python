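"""Low-level DNA sequence helpers shared across modules.

Bases are encoded as uint8: A=0, C=1, G=2, T=3.  Ambiguity codes in a
*read* encode to 4 and in a *reference* to 5, so that an N in a read never
matches anything — ambiguous bases always count as mismatches.
"""

from __future__ import annotations

import numpy as np

_READ_LUT = np.full(256, 4, dtype=np.uint8)
_REF_LUT = np.full(256, 5, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _READ_LUT[_b] = _i
    _READ_LUT[_b + 32] = _i  # lower case
    _REF_LUT[_b] = _i
    _REF_LUT[_b + 32] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

BASES = "ACGT"


def encode_read(seq: str) -> np.ndarray:
    """Encode a read sequence; non-ACGT -> 4 (never matches a reference)."""
    return _READ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_ref(seq: str) -> np.ndarray:
    """Encode a reference sequence; non-ACGT -> 5."""
    return _REF_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_read_matrix(seqs: list[str], length: int) -> np.ndarray:
    """Stack equal-length reads into an (n, length) uint8 matrix."""
    out = np.empty((len(seqs), length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"read {i} has length {len(s)}, expected {length}"
            )
        out[i] = encode_read(s)
    return out


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTNN"[b] for b in arr)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform i.i.d. DNA string of length n from a seeded generator."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y or x not in BASES for x, y in zip(a, b))
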