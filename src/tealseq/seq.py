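"""Low-level DNA sequence utilities shared across the toolkit.

Sequences are plain upper-case strings over the alphabet ACGTN at module
boundaries; hot loops work on numpy uint8 codes (A=0, C=1, G=2, T=3, N=4).
Any IUPAC ambiguity code other than ACGT collapses to N: probes are
synthesized oligos and must be fully specified, so N never matches anything.
"""

from __future__ import annotations

import numpy as np

CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
BASES = "ACGTN"
N_CODE = 4

_NORMALIZE = str.maketrans(
    "acgtnACGTN" + "RYSWKMBDHVryswkmbdhv" + "Uu",
    "ACGTNACGTN" + "N" * 20 + "TT",
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ENCODE_LUT = np.full(256, N_CODE, dtype=np.uint8)
for _b, _c in CODE.items():
    _ENCODE_LUT[ord(_b)] = _c


def normalize(seq: str) -> str:
    """Upper-case and collapse every non-ACGT character to N."""
    out = seq.translate(_NORMALIZE)
    if not set(out) <= set(BASES):
        bad = sorted(set(out) - set(BASES))
        raise ValueError(f"sequence contains non-nucleotide characters: {bad}")
    return out


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    best = 0
    run = 0
    prev = ""
    for b in seq:
        if b == prev:
            run += 1
        else:
            run = 1
            prev = b
        if run > best:
            best = run
    return best


def hamming(a: str, b: str) -> int:
    """Hamming distance; N mismatches everything including N."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    ca, cb = encode(a), encode(b)
    return int(np.sum((ca != cb) | (ca == N_CODE) | (cb == N_CODE)))


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random fully specified sequence with a target GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))
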