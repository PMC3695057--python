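"""Small sequence utilities shared across modules.

All sequences are canonicalized to the uppercase DNA alphabet (U -> T) at
load time; downstream code never sees RNA letters or lowercase.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")


def canonicalize(sequence: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T."""
    return sequence.strip().upper().replace("U", "T")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def validate_dna(sequence: str, *, allow_n: bool = True, context: str = "sequence") -> None:
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    bad = set(sequence) - alphabet
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in {context}")
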