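"""Nearest-neighbor DNA duplex thermodynamics.

Duplex stability is summarized by the stacking enthalpy summed over
consecutive dinucleotides, using the unified nearest-neighbor parameter set
(kcal/mol per stack, 37 C; initiation terms excluded since only differences
across a fixed-length window matter here).  The table is symmetric under
reverse complement, so the enthalpy of a window equals that of its reverse
complement.
"""

from __future__ import annotations

import warnings

NN_TABLE_VERSION = "unified-1998"

#: stacking enthalpy (kcal/mol) per dinucleotide step, 5'->3' top strand
NN_DELTA_H: dict[str, float] = {
    "AA": -7.9, "TT": -7.9,
    "AT": -7.2,
    "TA": -7.2,
    "CA": -8.5, "TG": -8.5,
    "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8,
    "GA": -8.2, "TC": -8.2,
    "CG": -10.6,
    "GC": -9.8,
    "GG": -8.0, "CC": -8.0,
}


def nn_enthalpy(seq: str) -> float:
    """Sum of nearest-neighbor stacking enthalpies over a sequence (kcal/mol).

    Sequences shorter than 2 nt have no stack and return 0 (with a
    warning); stacks containing a non-ACGT symbol are skipped with a
    warning.
    """
    s = str(seq).upper().replace("U", "T")
    if len(s) < 2:
        warnings.warn("nn_enthalpy: sequence shorter than 2 nt, returning 0", stacklevel=2)
        return 0.0
    total = 0.0
    skipped = 0
    for i in range(len(s) - 1):
        stack = s[i : i + 2]
        try:
            total += NN_DELTA_H[stack]
        except KeyError:
            skipped += 1
    if skipped:
        warnings.warn(
            f"nn_enthalpy: skipped {skipped} stack(s) containing ambiguous bases",
            stacklevel=2,
        )
    return total
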