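"""Bulge-aware pairwise alignment between an sgRNA spacer and a DNA site.

Cas9 tolerates not only mismatches but also single-nucleotide bulges on
either side of the RNA:DNA heteroduplex — an unpaired DNA base (DNA bulge)
or an unpaired RNA base (RNA bulge).  In alignment terms these are
single-column indels.  The aligner here is a global (Needleman–Wunsch style)
dynamic program with a hard budget on the number of indel columns (default
3), with no affine extension: adjacent gap columns are permitted but each
consumes one unit of the budget.

Because up to three indels are allowed, the genomic window opposite the
20-nt spacer may be anywhere from 17 to 23 nt.  :func:`align_best_window`
builds the seven windows anchored at the PAM-proximal end and keeps the
highest-scoring alignment.

Conventions
-----------
* Spacer and protospacer are both written 5'->3', so the *last* character is
  PAM-proximal.  Positions are numbered 1..20 from the PAM-proximal base.
* Genome coordinates are 0-based half-open on the forward strand; sites on
  the minus strand store the reverse-complemented (protospacer-sense)
  sequence.
* Tie-breaking between equal-score alignments: fewer gap columns first,
  then fewer mismatches, then the PAM-proximal-most gap placement (with a
  gap in the guide row preferred over a gap in the target row at the same
  column).  This makes the aligner fully deterministic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._kernel import batch_scores
from ._seq import clean_sequence, complement, encode, reverse_complement

SPACER_LENGTH = 20
MIN_WINDOW = 17
MAX_WINDOW = 23
#: window lengths tried by :func:`align_best_window`, PAM-anchored
WINDOW_LENGTHS = tuple(range(MIN_WINDOW, MAX_WINDOW + 1))


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GuideRNA:
    """A named 20-nt spacer (DNA alphabet, 5'->3', PAM-proximal end last)."""

    id: str
    spacer: str

    def __post_init__(self):
        object.__setattr__(self, "spacer", clean_sequence(self.spacer, name="spacer"))
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(
                f"guide {self.id!r}: spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}"
            )


@dataclass(frozen=True)
class TargetSite:
    """A stranded genomic protospacer window with its PAM and flanks.

    ``start``/``end`` delimit the protospacer on the forward strand
    (0-based, half-open); ``site_seq`` and ``pam`` are protospacer-sense,
    i.e. reverse-complemented for minus-strand sites.  Flanks are
    protospacer-sense as well: ``upstream_flank`` is 5' of the protospacer
    (PAM-distal), ``downstream_flank`` is 3' of the PAM.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    site_seq: str
    pam: str
    upstream_flank: str = ""
    downstream_flank: str = ""

    def __post_init__(self):
        object.__setattr__(self, "site_seq", clean_sequence(self.site_seq, name="site_seq"))
        object.__setattr__(self, "pam", clean_sequence(self.pam, name="pam"))
        object.__setattr__(
            self, "upstream_flank", clean_sequence(self.upstream_flank, name="upstream_flank")
        )
        object.__setattr__(
            self,
            "downstream_flank",
            clean_sequence(self.downstream_flank, name="downstream_flank"),
        )
        if not MIN_WINDOW <= len(self.site_seq) <= MAX_WINDOW:
            raise ValueError(
                f"site_seq length {len(self.site_seq)} outside {MIN_WINDOW}-{MAX_WINDOW}"
            )
        if len(self.pam) != 3:
            raise ValueError(f"PAM must be 3 nt, got {self.pam!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start != len(self.site_seq):
            raise ValueError("end - start must equal len(site_seq)")

    @property
    def pam_type(self) -> str:
        if self.pam[1:] == "GG":
            return "NGG"
        if self.pam[1:] == "AG":
            return "NAG"
        return "other"


@dataclass(frozen=True)
class AlignmentParams:
    """Match/mismatch/gap scoring with a hard gap budget."""

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.25
    max_gaps: int = 3

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match reward must be > 0")
        if self.mismatch > 0:
            raise ValueError("mismatch penalty must be <= 0")
        if self.gap >= 0:
            raise ValueError("gap penalty must be < 0")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class GuideTargetAlignment:
    """An optimal gapped alignment and its decomposition.

    ``aligned_guide`` and ``aligned_target`` are equal-length strings whose
    rightmost column is PAM-proximal.  A ``-`` in the guide row is a DNA
    bulge (unpaired DNA base); in the target row, an RNA bulge.
    ``mismatch_positions`` are spacer positions 1..20 counted from the
    PAM-proximal base; ``mismatch_pairs`` hold (guide base, opposing
    target-strand base), the latter being the complement of the
    protospacer-sense base the guide faces.
    """

    aligned_guide: str
    aligned_target: str
    score: float
    n_match: int
    n_mismatch: int
    n_dna_bulge: int
    n_rna_bulge: int
    mismatch_positions: tuple[int, ...]
    mismatch_pairs: tuple[tuple[str, str], ...]
    chosen_window: int

    @property
    def n_bulges(self) -> int:
        return self.n_dna_bulge + self.n_rna_bulge

    def bulge_positions(self) -> tuple[int, ...]:
        """Spacer positions (1..20, PAM-proximal first) of bulge columns.

        An RNA bulge takes the position of its unpaired guide base; a DNA
        bulge takes the position of the nearest guide base on its
        PAM-proximal side (1 if the bulge is the PAM-proximal-most column).
        """
        out = []
        guide_bases_right = 0
        for gc_, tc in zip(reversed(self.aligned_guide), reversed(self.aligned_target)):
            if gc_ != "-":
                guide_bases_right += 1
                if tc == "-":
                    out.append(guide_bases_right)
            else:
                out.append(max(guide_bases_right, 1))
        return tuple(sorted(out))


# ---------------------------------------------------------------------------
# single-pair DP with traceback


def align_fixed(
    guide: str | GuideRNA, target: str, params: AlignmentParams = DEFAULT_PARAMS
) -> GuideTargetAlignment:
    """Optimal gap-budgeted global alignment of a spacer to one DNA window.

    Returns the maximum-score alignment among all global alignments using at
    most ``params.max_gaps`` single-column indels, resolved deterministically
    by the module-level tie-break rule.
    """
    gseq = guide.spacer if isinstance(guide, GuideRNA) else clean_sequence(guide, name="guide")
    tseq = clean_sequence(target, name="target")
    if not MIN_WINDOW <= len(tseq) <= MAX_WINDOW:
        raise ValueError(f"target length {len(tseq)} outside {MIN_WINDOW}-{MAX_WINDOW}")
    return _align_core(gseq, tseq, params, chosen_window=len(tseq))


def _align_core(gseq, tseq, params, chosen_window):
    m, n = len(gseq), len(tseq)
    G = params.max_gaps
    if abs(m - n) > G:
        raise ValueError(f"length difference {abs(m - n)} exceeds gap budget {G}")
    NEG = (float("-inf"), 0)
    # value[(g, i, j)] = (score, -n_mismatch); score maximized, then fewest
    # mismatches within each gap layer; fewest gaps resolved at the end.
    val = {}
    for g in range(G + 1):
        for i in range(m + 1):
            for j in range(n + 1):
                if i == 0 and j == 0:
                    val[g, i, j] = (0.0, 0) if g == 0 else NEG
                    continue
                best = NEG
                if i > 0 and j > 0:
                    s = params.match if gseq[i - 1] == tseq[j - 1] else params.mismatch
                    dmis = 0 if gseq[i - 1] == tseq[j - 1] else 1
                    p = val[g, i - 1, j - 1]
                    cand = (p[0] + s, p[1] - dmis)
                    if cand > best:
                        best = cand
                if g > 0:
                    if j > 0:
                        p = val[g - 1, i, j - 1]
                        cand = (p[0] + params.gap, p[1])
                        if cand > best:
                            best = cand
                    if i > 0:
                        p = val[g - 1, i - 1, j]
                        cand = (p[0] + params.gap, p[1])
                        if cand > best:
                            best = cand
                val[g, i, j] = best
    # final state: max score, then fewest gaps, then fewest mismatches
    g_best = max(
        range(G + 1),
        key=lambda g: (round(val[g, m, n][0], 9), -g, val[g, m, n][1]),
    )
    score, neg_mis = val[g_best, m, n]

    # traceback right-to-left; preferring gap moves first places gaps at the
    # PAM-proximal-most admissible columns (guide-row gap before target-row)
    def _eq(cand, cur):
        return abs(cand[0] - cur[0]) < 1e-9 and cand[1] == cur[1]

    rows_g, rows_t = [], []
    i, j, g = m, n, g_best
    cur = val[g, i, j]
    while i > 0 or j > 0:
        moved = False
        if g > 0 and j > 0:
            p = val[g - 1, i, j - 1]
            if _eq((p[0] + params.gap, p[1]), cur):
                rows_g.append("-")
                rows_t.append(tseq[j - 1])
                j, g = j - 1, g - 1
                cur = p
                moved = True
        if not moved and g > 0 and i > 0:
            p = val[g - 1, i - 1, j]
            if _eq((p[0] + params.gap, p[1]), cur):
                rows_g.append(gseq[i - 1])
                rows_t.append("-")
                i, g = i - 1, g - 1
                cur = p
                moved = True
        if not moved:
            s = params.match if gseq[i - 1] == tseq[j - 1] else params.mismatch
            dmis = 0 if gseq[i - 1] == tseq[j - 1] else 1
            p = val[g, i - 1, j - 1]
            assert _eq((p[0] + s, p[1] - dmis), cur), "traceback inconsistency"
            rows_g.append(gseq[i - 1])
            rows_t.append(tseq[j - 1])
            i, j = i - 1, j - 1
            cur = p
            moved = True
    aligned_guide = "".join(reversed(rows_g))
    aligned_target = "".join(reversed(rows_t))
    return _build_alignment(aligned_guide, aligned_target, params, chosen_window)


def _build_alignment(aligned_guide, aligned_target, params, chosen_window):
    n_match = n_mismatch = n_dna = n_rna = 0
    mis_pos, mis_pairs = [], []
    guide_pos = 0  # counted from the PAM-proximal (right) end
    for gc_, tc in zip(reversed(aligned_guide), reversed(aligned_target)):
        if gc_ == "-":
            n_dna += 1
            continue
        guide_pos += 1
        if tc == "-":
            n_rna += 1
        elif gc_ == tc:
            n_match += 1
        else:
            n_mismatch += 1
            mis_pos.append(guide_pos)
            mis_pairs.append((gc_, complement(tc)))
    score = params.match * n_match + params.mismatch * n_mismatch + params.gap * (n_dna + n_rna)
    return GuideTargetAlignment(
        aligned_guide=aligned_guide,
        aligned_target=aligned_target,
        score=score,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_dna_bulge=n_dna,
        n_rna_bulge=n_rna,
        mismatch_positions=tuple(sorted(mis_pos)),
        mismatch_pairs=tuple(mis_pairs),
        chosen_window=chosen_window,
    )


# ---------------------------------------------------------------------------
# PAM-anchored window search


def candidate_windows(site: TargetSite) -> dict[int, str]:
    """The 17-23 nt windows immediately 5' of the PAM, by length.

    Windows longer than the stored protospacer borrow bases from the
    PAM-distal (upstream) flank; shorter ones trim the PAM-distal end.
    Lengths that cannot be built from the available flank are dropped with a
    warning.
    """
    extended = site.upstream_flank + site.site_seq
    out = {}
    for w in WINDOW_LENGTHS:
        if w <= len(extended):
            out[w] = extended[-w:]
    if len(out) < len(WINDOW_LENGTHS):
        warnings.warn(
            f"site {site.seq_id}:{site.start}-{site.end}: insufficient PAM-distal flank, "
            f"only window lengths {sorted(out)} constructible",
            stacklevel=2,
        )
    if not out:
        raise ValueError("no candidate window constructible for site")
    return out


def align_best_window(
    guide: GuideRNA | str, site: TargetSite, params: AlignmentParams = DEFAULT_PARAMS
) -> GuideTargetAlignment:
    """Best alignment over the seven PAM-anchored windows (lengths 17-23).

    Ties on score prefer the window closest to 20 nt, then the shorter one.
    """
    windows = candidate_windows(site)
    best = None
    best_key = None
    for w in sorted(windows, key=lambda w: (abs(w - SPACER_LENGTH), w)):
        if abs(w - SPACER_LENGTH) > params.max_gaps:
            continue  # window needs more indels than the budget allows
        aln = align_fixed(guide, windows[w], params)
        key = round(aln.score, 9)
        if best is None or key > best_key:
            best, best_key = aln, key
    return best


def align_best_window_many(
    guide: GuideRNA | str,
    sites: Sequence[TargetSite],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[GuideTargetAlignment]:
    """Full best-window alignments for many sites of one guide.

    Window choice is made with the batched kernel (one pass per window
    length); only the chosen window of each site is then traced back, so
    results equal ``[align_best_window(guide, s, params) for s in sites]``
    at a fraction of the cost.
    """
    gseq = guide.spacer if isinstance(guide, GuideRNA) else clean_sequence(guide)
    gcodes = encode(gseq)
    n = len(sites)
    # per-site best (key, window, sequence); key mirrors align_best_window's
    # tie-break: score desc, |w-20| asc, w asc
    best: list[tuple[tuple, int, str] | None] = [None] * n
    by_length: dict[int, tuple[list[int], list[str]]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, site in enumerate(sites):
            for w, seq in candidate_windows(site).items():
                if abs(w - SPACER_LENGTH) > params.max_gaps:
                    continue
                idxs, seqs = by_length.setdefault(w, ([], []))
                idxs.append(idx)
                seqs.append(seq)
    for w, (idxs, seqs) in by_length.items():
        scores = batch_scores(
            gcodes,
            np.stack([encode(s) for s in seqs]),
            params.match, params.mismatch, params.gap, params.max_gaps,
        )
        for idx, seq, sc in zip(idxs, seqs, scores):
            key = (-round(sc, 9), abs(w - SPACER_LENGTH), w)
            if best[idx] is None or key < best[idx][0]:
                best[idx] = (key, w, seq)
    out = []
    for idx, entry in enumerate(best):
        if entry is None:
            raise ValueError(f"no constructible window for site index {idx}")
        _, w, seq = entry
        out.append(_align_core(gseq, seq, params, chosen_window=w))
    return out


def best_window_scores(
    guide: GuideRNA | str,
    sites: Sequence[TargetSite],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Vectorized best-of-7-window scores for many sites of one guide.

    Equivalent to ``[align_best_window(guide, s, params).score for s in
    sites]`` but runs the batched DP kernel once per window length.
    """
    gseq = guide.spacer if isinstance(guide, GuideRNA) else clean_sequence(guide)
    gcodes = encode(gseq)
    n = len(sites)
    scores = np.full(n, -np.inf)
    by_length: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    for idx, site in enumerate(sites):
        for w, seq in candidate_windows(site).items():
            if abs(w - SPACER_LENGTH) > params.max_gaps:
                continue
            idxs, rows = by_length.setdefault(w, ([], []))
            idxs.append(idx)
            rows.append(encode(seq))
    for w, (idxs, rows) in by_length.items():
        s = batch_scores(
            gcodes, np.stack(rows), params.match, params.mismatch, params.gap, params.max_gaps
        )
        np.maximum.at(scores, np.asarray(idxs), s)
    return scores


# ---------------------------------------------------------------------------
# match profiles: grid-free sufficient statistics for parameter search


@dataclass(frozen=True)
class MatchProfiles:
    """Per-site maximum match counts by (window length, gap count).

    With the match reward fixed, the optimal score of a window under any
    (mismatch, gap) penalty pair is a closed-form function of the maximum
    number of matched columns achievable with exactly g gap columns: in a
    window of length w aligned to a 20-nt spacer with g gaps, the number of
    paired columns is fixed at w - (g + w - 20)/2, so mismatches are
    determined by matches.  Computing these counts once per guide makes a
    dense penalty-grid search essentially free.
    """

    window_lengths: tuple[int, ...]
    #: (n_sites, n_windows, max_gaps+1); large-negative = infeasible
    matches: np.ndarray
    max_gaps: int

    def scores(self, params: AlignmentParams) -> np.ndarray:
        """Best-over-windows-and-gap-layers score per site under params."""
        if params.max_gaps > self.max_gaps:
            raise ValueError("profile built with a smaller gap budget")
        best = np.full(self.matches.shape[0], -np.inf)
        for wi, w in enumerate(self.window_lengths):
            for g in range(params.max_gaps + 1):
                M = self.matches[:, wi, g]
                a = (g + w - SPACER_LENGTH) / 2.0  # gaps in the guide row
                if a != int(a) or a < 0 or a > g:
                    continue
                n_pair = w - a
                s = params.match * M + params.mismatch * (n_pair - M) + params.gap * g
                s = np.where(M < -1e20, -np.inf, s)
                np.maximum(best, s, out=best)
        return best


def match_profiles(
    guide: GuideRNA | str, sites: Sequence[TargetSite], max_gaps: int = 3
) -> MatchProfiles:
    """Compute :class:`MatchProfiles` for many sites of one guide."""
    from ._kernel import batch_layer_finals

    gseq = guide.spacer if isinstance(guide, GuideRNA) else clean_sequence(guide)
    gcodes = encode(gseq)
    n = len(sites)
    M = np.full((n, len(WINDOW_LENGTHS), max_gaps + 1), -np.inf)
    by_length: dict[int, tuple[list[int], list[np.ndarray]]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for idx, site in enumerate(sites):
            for w, seq in candidate_windows(site).items():
                idxs, rows = by_length.setdefault(w, ([], []))
                idxs.append(idx)
                rows.append(encode(seq))
    for w, (idxs, rows) in by_length.items():
        finals = batch_layer_finals(gcodes, np.stack(rows), 1.0, 0.0, 0.0, max_gaps)
        wi = WINDOW_LENGTHS.index(w)
        M[np.asarray(idxs), wi, :] = finals
    return MatchProfiles(WINDOW_LENGTHS, M, max_gaps)


# ---------------------------------------------------------------------------
# alignment-parameter optimization


def default_param_grid() -> list[AlignmentParams]:
    """Match fixed at 1; mismatch 0..-1.5 and gap -0.25..-3.0 in 0.25 steps."""
    mismatches = [round(-0.25 * k, 2) for k in range(0, 7)]
    gaps = [round(-0.25 * k, 2) for k in range(1, 13)]
    return [AlignmentParams(1.0, mm, gp, 3) for mm in mismatches for gp in gaps]


def is_exact_match(guide: GuideRNA, site: TargetSite) -> bool:
    """True when the 20-nt PAM-anchored window equals the spacer exactly."""
    extended = site.upstream_flank + site.site_seq
    return extended[-SPACER_LENGTH:] == guide.spacer


def optimize_params(
    records: Iterable[tuple[GuideRNA, TargetSite, float]],
    grid: Sequence[AlignmentParams] | None = None,
) -> AlignmentParams:
    """Pick alignment parameters maximizing the mean per-guide r^2.

    For every grid point, each guide's best-of-window scores are correlated
    (squared Pearson) with the observed cleavage frequencies over its
    non-exact-match targets; the grid point with the highest mean across
    guides wins.  Ties prefer the least-negative gap penalty, then the
    least-negative mismatch penalty.  Exact-match targets are removed first
    because they always reach the maximal score.
    """
    grid = list(grid) if grid is not None else default_param_grid()
    if not grid:
        raise ValueError("empty parameter grid")
    per_guide: dict[str, tuple[GuideRNA, list[TargetSite], list[float]]] = {}
    for g, site, freq in records:
        entry = per_guide.setdefault(g.id, (g, [], []))
        if is_exact_match(g, site):
            continue
        entry[1].append(site)
        entry[2].append(float(freq))
    usable = {
        gid: e
        for gid, e in per_guide.items()
        if len(e[1]) >= 2 and len(set(e[2])) > 1
    }
    if not usable:
        names = ", ".join(sorted(per_guide)) or "<none>"
        raise ValueError(
            f"no guide with >=2 non-exact-match targets and varying frequencies (guides: {names})"
        )

    profiles = {
        gid: (match_profiles(g, sites, max_gaps=max(p.max_gaps for p in grid)), np.asarray(freqs))
        for gid, (g, sites, freqs) in usable.items()
    }
    best_params, best_key = None, None
    for p in grid:
        r2s = []
        for gid, (prof, freqs) in profiles.items():
            s = prof.scores(p)
            if np.all(s == s[0]):
                continue
            r, _ = stats.pearsonr(s, freqs)
            if np.isnan(r):
                continue
            r2s.append(r * r)
        mean_r2 = float(np.mean(r2s)) if r2s else float("-inf")
        # ties: least-negative gap, then least-negative mismatch
        key = (round(mean_r2, 12), p.gap, p.mismatch)
        if best_key is None or key > best_key:
            best_params, best_key = p, key
    if best_params is None or best_key[0] == float("-inf"):
        raise ValueError(
            "degenerate optimization: constant alignment scores for every grid point "
            f"(guides: {', '.join(sorted(usable))})"
        )
    return best_params


# ---------------------------------------------------------------------------
# PAM relocation


_PAM_SHIFT_ORDER = (0, 1, -1, 2, -2)  # |shift| ascending, downstream before upstream


def _oriented_slice(genome: Mapping[str, str], seq_id: str, start: int, end: int, strand: str) -> str:
    contig = genome[seq_id]
    if start < 0 or end > len(contig):
        raise ValueError(f"coordinates [{start}, {end}) outside contig {seq_id!r}")
    s = contig[start:end]
    return reverse_complement(s) if strand == "-" else s


def relocate_pam(site: TargetSite, genome: Mapping[str, str]) -> TargetSite:
    """Shift a non-NGG site's PAM by up to 2 nt toward the nearest NGG/NAG.

    Searches shifts 0, +1, -1, +2, -2 (downstream first, in the site's
    strand orientation) for an NGG PAM; if none exists at any shift, repeats
    the search for NAG; otherwise returns the site unchanged.  The
    protospacer window moves with the PAM.
    """
    contig = genome[site.seq_id]
    if site.start < 0 or site.end > len(contig):
        raise ValueError(f"site coordinates outside contig {site.seq_id!r}")
    for motif in ("GG", "AG"):
        for shift in _PAM_SHIFT_ORDER:
            cand = site if shift == 0 else _shifted_site(site, genome, shift)
            if cand is None:
                continue
            if cand.pam[1:] == motif:
                return cand
    return site


def _shifted_site(site: TargetSite, genome: Mapping[str, str], shift: int) -> TargetSite | None:
    """The site moved ``shift`` nt downstream (3') in protospacer orientation."""
    contig = genome[site.seq_id]
    L = site.end - site.start
    if site.strand == "+":
        start, end = site.start + shift, site.end + shift
        pam_lo, pam_hi = end, end + 3
    else:
        start, end = site.start - shift, site.end - shift
        pam_lo, pam_hi = start - 3, start
    if start < 0 or end > len(contig) or pam_lo < 0 or pam_hi > len(contig):
        return None
    site_seq = _oriented_slice(genome, site.seq_id, start, end, site.strand)
    pam = _oriented_slice(genome, site.seq_id, pam_lo, pam_hi, site.strand)
    up, down = extract_flanks(genome, site.seq_id, start, end, site.strand)
    return replace(
        site,
        start=start,
        end=end,
        site_seq=site_seq,
        pam=pam,
        upstream_flank=up,
        downstream_flank=down,
    )


def extract_flanks(
    genome: Mapping[str, str],
    seq_id: str,
    start: int,
    end: int,
    strand: str,
    flank: int = 100,
) -> tuple[str, str]:
    """Protospacer-sense (upstream, downstream) flanks, trimmed at contig ends.

    The downstream flank starts beyond the 3-nt PAM.
    """
    contig = genome[seq_id]
    if strand == "+":
        up = contig[max(0, start - flank) : start]
        down = contig[end + 3 : end + 3 + flank]
        return up, down
    up = reverse_complement(contig[end : end + flank])
    down = reverse_complement(contig[max(0, start - 3 - flank) : max(0, start - 3)])
    return up, down
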