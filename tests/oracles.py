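"""Independent oracles used by the test suite.

These deliberately avoid the package's dynamic-programming machinery:
``enumerate_best_score`` lays out every admissible placement of gap columns
explicitly and scores each candidate alignment from scratch.
"""

from __future__ import annotations

import itertools


def enumerate_best_score(
    guide: str,
    target: str,
    match: float,
    mismatch: float,
    gap: float,
    max_gaps: int,
) -> float:
    """Best global alignment score by exhaustive gap-placement enumeration.

    An alignment with ``a`` gap columns in the guide row and ``b`` in the
    target row has ``len(guide) + a == len(target) + b`` columns; gap-vs-gap
    columns are disallowed.  All (a, b) with a + b <= max_gaps and all
    disjoint placements of those columns are scored.
    """
    m, n = len(guide), len(target)
    best = float("-inf")
    for a in range(0, max_gaps + 1):
        b = a - (n - m)
        if b < 0 or a + b > max_gaps:
            continue
        ncols = m + a
        for guide_gap_cols in itertools.combinations(range(ncols), a):
            rest = [c for c in range(ncols) if c not in guide_gap_cols]
            for target_gap_cols in itertools.combinations(rest, b):
                tg = set(target_gap_cols)
                gi = ti = 0
                score = 0.0
                for c in range(ncols):
                    if c in guide_gap_cols:
                        score += gap
                        ti += 1
                    elif c in tg:
                        score += gap
                        gi += 1
                    else:
                        score += match if guide[gi] == target[ti] else mismatch
                        gi += 1
                        ti += 1
                best = max(best, score)
    return best
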