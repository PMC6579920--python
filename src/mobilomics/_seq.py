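"""Small shared sequence helpers."""

from __future__ import annotations

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def validate_dna(seq: str, name: str = "sequence") -> None:
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-DNA symbols: {sorted(bad)}")


def validate_protein(seq: str, name: str = "sequence") -> None:
    bad = set(seq.upper()) - AA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-amino-acid symbols: {sorted(bad)}")
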