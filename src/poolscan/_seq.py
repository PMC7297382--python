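"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 codes: A=0, C=1, G=2, T=3, gap/other=4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform-random A/C/G/T string of the given length."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; code 4 becomes '-'."""
    lut = np.array(list(BASES + "-"))
    return "".join(lut[codes])


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Return a copy of ``seq`` with substitutions applied at the given per-base rate.

    Substituted bases are drawn uniformly from the three non-matching bases.
    """
    if rate <= 0:
        return seq
    codes = encode(seq).copy()
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    if hits.size:
        # shift by 1..3 mod 4 guarantees a different base
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return decode(codes)
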