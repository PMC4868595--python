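"""Small nucleotide-sequence utilities shared across the package.

Sequences are plain uppercase ACGT strings; genomes are ``dict`` objects
mapping contig name to sequence.  Coordinates are 1-based inclusive
throughout the package.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

# index lookup: byte value -> 0..3, 255 for non-ACGT
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 array of base indices (A=0..T=3)."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASE_BYTES[arr].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random ACGT sequence with the requested expected GC fraction."""
    if length == 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))
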