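"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# stable code assignment used by the vectorized alignment kernel
_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def clean_sequence(seq: str, *, name: str = "sequence") -> str:
    """Upper-case, map U->T, and validate an ACGT string."""
    s = str(seq).strip().upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{name} contains non-ACGT symbols: {sorted(bad)}")
    return s


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as uint8 codes 0..3."""
    return np.array([_CODES[c] for c in seq], dtype=np.uint8)


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)
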