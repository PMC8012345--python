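"""Small shared helpers: sequence arithmetic and codon tables."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# standard genetic code, DNA codons
CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _a in enumerate(_aas):
    CODON_TABLE["".join((_bases[_i // 16], _bases[(_i // 4) % 4], _bases[_i % 4]))] = _a

STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame DNA string; trailing partial codon ignored."""
    return "".join(
        CODON_TABLE.get(cds[i : i + 3].upper(), "X") for i in range(0, len(cds) - 2, 3)
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def random_orf_codons(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame sequence of n_codons sense (non-stop) codons."""
    sense = sorted(set(CODON_TABLE) - STOP_CODONS)
    idx = rng.integers(0, len(sense), size=n_codons)
    return "".join(sense[i] for i in idx)


def seq_identity(a: str, b: str) -> float:
    """Gap-free percent identity of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if not a:
        return 0.0
    m = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * m / len(a)


def encode(seq: str) -> np.ndarray:
    """A/C/G/T/other -> 0/1/2/3/4 uint8 array."""
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
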