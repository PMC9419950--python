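"""Small nucleotide-sequence helpers used throughout the package."""

from __future__ import annotations

from .errors import AlphabetError

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_dna(seq: str, name: str = "sequence") -> str:
    """Return *seq* uppercased, raising :class:`AlphabetError` on non-ACGT."""
    up = seq.upper()
    if not set(up) <= DNA_ALPHABET:
        bad = sorted(set(up) - DNA_ALPHABET)
        raise AlphabetError(f"{name} contains non-ACGT symbols: {bad}")
    return up


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
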