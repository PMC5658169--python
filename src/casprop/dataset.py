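"""Training-set assembly: mined negatives, deduplication, balanced resampling.

The cleaved (positive) records come from the assays; the uncleaved
(negative) class is mined from the genome: every NGG/NAG-adjacent window on
either strand is aligned to the guide and kept when its best-window score
exceeds a complementarity threshold (default 14.75, the 5th percentile of
scores among cleaved sites) and it does not overlap a known cleaved site of
that guide.

Because negatives vastly outnumber positives, each training round balances
the classes per guide: positives are bootstrapped (with replacement) to
twice their original count, and an equal number of negatives is drawn
without replacement — majority under-sampling combined with minority
over-sampling.  Averaging over many such rounds (default 100) gives the
ensemble its stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import (
    AlignmentParams,
    DEFAULT_PARAMS,
    GuideRNA,
    TargetSite,
    best_window_scores,
    extract_flanks,
)
from ._seq import reverse_complement

#: alignment-score threshold for mined uncleaved candidates (strict >)
MIN_NEGATIVE_SCORE = 14.75

#: per-round class ratios: positives bootstrapped to 2x, negatives matched
OVERSAMPLE_FACTOR = 2

DEFAULT_EXCLUDED_STUDIES = ("Frock",)
DEFAULT_REFERENCE_STUDY = "Tsai"


def _pam_hits(seq: str, pams: Sequence[str]) -> Iterable[tuple[int, str]]:
    """Yield (pam_start_on_forward, strand) for NGG/NAG-style motifs."""
    want_gg = any(p.endswith("GG") for p in pams)
    want_ag = any(p.endswith("AG") for p in pams)
    n = len(seq)
    for i in range(n - 2):
        two = seq[i + 1 : i + 3]
        if (want_gg and two == "GG") or (want_ag and two == "AG"):
            yield i, "+"
        two = seq[i : i + 2]
        if (want_gg and two == "CC") or (want_ag and two == "CT"):
            yield i, "-"


def mine_negatives(
    guide: GuideRNA,
    genome: Mapping[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
    min_score: float = MIN_NEGATIVE_SCORE,
    pams: Sequence[str] = ("NGG", "NAG"),
    exclude_intervals: Sequence[tuple[str, int, int]] = (),
    flank: int = 100,
) -> list[TargetSite]:
    """Exhaustively scan a genome for uncleaved candidate sites of a guide.

    Both strands are scanned for PAM motifs; the 20-nt window 5' of each
    PAM (plus enough PAM-distal flank for the 17-23 nt window search) is
    aligned to the spacer, and sites scoring strictly above ``min_score``
    that do not overlap ``exclude_intervals`` (the guide's known cleaved
    sites, as (seq_id, start, end)) are returned.
    """
    from ._kernel import batch_scores
    from ._seq import encode
    from .align import MAX_WINDOW, WINDOW_LENGTHS

    # phase 1: cheap scan, scoring encoded 23-nt windows in bulk
    meta: list[tuple[str, int, int, str]] = []  # (seq_id, start, end, strand)
    ext_rows: list[np.ndarray] = []
    for seq_id, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        excl = [(s, e) for (c, s, e) in exclude_intervals if c == seq_id]
        for pam_pos, strand in _pam_hits(seq, pams):
            if strand == "+":
                start, end = pam_pos - 20, pam_pos
                if start < MAX_WINDOW - 20 or pam_pos + 3 > n:
                    continue
                ext = seq[end - MAX_WINDOW : end]
            else:
                start, end = pam_pos + 3, pam_pos + 23
                if end + (MAX_WINDOW - 20) > n:
                    continue
                ext = reverse_complement(seq[start : start + MAX_WINDOW])
            if any(s < end and e > start for (s, e) in excl):
                continue
            if "N" in ext:
                continue
            meta.append((seq_id, start, end, strand))
            ext_rows.append(encode(ext))
    if not meta:
        return []
    arr = np.stack(ext_rows)
    scores = np.full(len(meta), -np.inf)
    for w in WINDOW_LENGTHS:
        s = batch_scores(
            encode(guide.spacer), arr[:, MAX_WINDOW - w :],
            params.match, params.mismatch, params.gap, params.max_gaps,
        )
        np.maximum(scores, s, out=scores)

    # phase 2: materialize sites (with flanks) only above the threshold
    out: list[TargetSite] = []
    for (seq_id, start, end, strand), sc in zip(meta, scores):
        if sc <= min_score:
            continue
        seq = genome[seq_id]
        if strand == "+":
            site_seq = seq[start:end]
            pam = seq[end : end + 3]
        else:
            site_seq = reverse_complement(seq[start:end])
            pam = reverse_complement(seq[start - 3 : start])
        up, down = extract_flanks(genome, seq_id, start, end, strand, flank=flank)
        out.append(
            TargetSite(seq_id, start, end, strand, site_seq, pam,
                       upstream_flank=up, downstream_flank=down)
        )
    return out


def deduplicate(
    records: pd.DataFrame,
    reference_study: str = DEFAULT_REFERENCE_STUDY,
    exclude_studies: Sequence[str] = DEFAULT_EXCLUDED_STUDIES,
) -> pd.DataFrame:
    """Resolve guides profiled by several studies down to one collection.

    Records from excluded studies are dropped outright.  For a guide
    present in multiple remaining studies, the reference study's collection
    is kept; if the reference did not profile that guide, the study with
    the most targets is kept (with a warning).
    """
    df = records[~records["study"].isin(exclude_studies)].copy()
    keep = []
    for gid, sub in df.groupby("guide_id", sort=False):
        studies = sub["study"].unique()
        if len(studies) == 1:
            keep.append(sub)
            continue
        if reference_study in studies:
            keep.append(sub[sub["study"] == reference_study])
        else:
            counts = sub.groupby("study").size().sort_values(ascending=False)
            chosen = counts.index[0]
            warnings.warn(
                f"guide {gid!r}: reference study {reference_study!r} missing; "
                f"keeping {chosen!r} ({counts.iloc[0]} targets)",
                stacklevel=2,
            )
            keep.append(sub[sub["study"] == chosen])
    if not keep:
        return df.iloc[0:0]
    return pd.concat(keep).sort_index()


@dataclass
class TrainingDataset:
    """Assembled positives (target_value > 0 scale) and mined negatives."""

    positives: pd.DataFrame
    negatives: pd.DataFrame

    def __post_init__(self):
        keys = [c for c in ("guide_id", "chrom", "start", "end")
                if c in self.positives.columns]
        if len(keys) >= 2:
            dup = self.positives.duplicated(subset=keys)
            if dup.any():
                raise ValueError("duplicated (guide, site) pairs among positives")

    def guides(self) -> list[str]:
        return sorted(set(self.positives["guide_id"]))


@dataclass
class SampledDataset:
    """One balanced training round: 2x bootstrapped positives + matched negatives."""

    records: pd.DataFrame
    round_seed: int


def sample_round(dataset: TrainingDataset, seed: int) -> SampledDataset:
    """Draw one class-balanced round (per guide) with a fixed seed."""
    rng = np.random.default_rng(seed)
    parts = []
    for gid in dataset.guides():
        pos = dataset.positives[dataset.positives["guide_id"] == gid]
        neg = dataset.negatives[dataset.negatives["guide_id"] == gid]
        n_target = OVERSAMPLE_FACTOR * len(pos)
        if len(pos) == 0:
            raise ValueError(f"guide {gid!r} has no positives")
        if len(neg) < n_target:
            raise ValueError(
                f"guide {gid!r}: {len(neg)} negatives available, {n_target} required"
            )
        boot = pos.sample(n=n_target, replace=True, random_state=rng.integers(2**31))
        drawn = neg.sample(n=n_target, replace=False, random_state=rng.integers(2**31))
        parts.append(boot)
        parts.append(drawn)
    return SampledDataset(pd.concat(parts, ignore_index=False), int(seed))


def round_seeds(master_seed: int, n_rounds: int) -> list[int]:
    """Stable per-round seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_rounds)]
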