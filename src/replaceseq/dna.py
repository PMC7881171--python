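"""Small DNA string helpers shared across the package.

Sequences are plain upper-case ``str`` over the alphabet ACGT (N tolerated
where noted). Coordinates everywhere in this package are 0-based, half-open;
cut positions are inter-base coordinates.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

def revcomp(seq: str) -> str:
    """Reverse complement of *seq*."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str, allow_n: bool = False) -> bool:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    return all(c in alphabet for c in seq)


def is_ngg(triplet: str) -> bool:
    """True iff *triplet* is an SpyCas9 NGG PAM."""
    return len(triplet) == 3 and triplet[0] in "ACGT" and triplet[1:] == "GG"


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Random uniform DNA of length *n* (fast path for megabase scales)."""
    idx = rng.integers(0, 4, size=n)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def hamming(a: str, b: str) -> int:
    """Hamming distance over the common prefix length (lengths must match)."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
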