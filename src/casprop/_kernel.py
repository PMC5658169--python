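"""Vectorized score-only alignment kernel.

Global alignment of one spacer against a batch of equal-length DNA windows
under a hard budget of single-column indels.  Only the optimal score is
produced; traceback (and the deterministic tie-break rule) lives in
:mod:`casprop.align`, which handles one pair at a time.  Scores from the two
routes agree exactly, which the test suite checks against a brute-force
enumeration oracle.
"""

from __future__ import annotations

import numpy as np

NEG = np.float32(-1e30)

_CHUNK = 20_000


def batch_scores(
    guide_codes: np.ndarray,
    target_codes: np.ndarray,
    match: float,
    mismatch: float,
    gap: float,
    max_gaps: int,
) -> np.ndarray:
    """Optimal gap-budgeted global alignment score for each target row.

    Parameters
    ----------
    guide_codes : (m,) uint8 array, spacer encoded 0..3.
    target_codes : (N, L) uint8 array of candidate windows, all length L.
    """
    finals = batch_layer_finals(guide_codes, target_codes, match, mismatch, gap, max_gaps)
    return finals.max(axis=1)


def batch_layer_finals(
    guide_codes: np.ndarray,
    target_codes: np.ndarray,
    match: float,
    mismatch: float,
    gap: float,
    max_gaps: int,
) -> np.ndarray:
    """(N, max_gaps+1) optimal score using *exactly* g gap columns.

    Infeasible layers (parity or length constraints) are a large negative
    sentinel.  With match=1, mismatch=0, gap=0 this yields the maximum
    number of matched columns per gap count — the sufficient statistic from
    which the score under any (mismatch, gap) penalty pair follows in
    closed form.
    """
    out = np.empty((target_codes.shape[0], max_gaps + 1), dtype=np.float64)
    for lo in range(0, target_codes.shape[0], _CHUNK):
        chunk = target_codes[lo : lo + _CHUNK]
        out[lo : lo + chunk.shape[0]] = _batch_layers_chunk(
            guide_codes, chunk, match, mismatch, gap, max_gaps
        )
    return out


def _batch_layers_chunk(guide, targets, match, mismatch, gap, max_gaps):
    m = guide.shape[0]
    n_batch, L = targets.shape
    if abs(m - L) > max_gaps:
        raise ValueError(f"length difference {abs(m - L)} exceeds gap budget {max_gaps}")
    G = int(max_gaps)
    if n_batch == 0:
        return np.empty((0, G + 1), dtype=np.float64)

    # substitution scores: subst[b, i, j] for guide[i] vs targets[b, j]
    eq = targets[:, None, :] == guide[None, :, None]
    subst = np.where(eq, np.float32(match), np.float32(mismatch))

    S = np.full((G + 1, m + 1, L + 1, n_batch), NEG, dtype=np.float32)
    for g in range(G + 1):
        if g == 0:
            S[g, 0, 0] = 0.0
        if g >= 1:
            if g <= m:
                S[g, g, 0] = g * gap
            if g <= L:
                S[g, 0, g] = g * gap
        for i in range(1, m + 1):
            for j in range(1, L + 1):
                best = S[g, i - 1, j - 1] + subst[:, i - 1, j - 1]
                if g > 0:
                    np.maximum(best, S[g - 1, i, j - 1] + np.float32(gap), out=best)
                    np.maximum(best, S[g - 1, i - 1, j] + np.float32(gap), out=best)
                S[g, i, j] = best
    return S[:, m, L].T.astype(np.float64)
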