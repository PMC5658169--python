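"""Synthetic genomes, guides, planted targets, and multi-study read counts.

The generator emulates the structure of genome-wide cleavage profiling
data at desk scale: a random genome; a handful of guides; per guide a set
of cleaved sites planted with controlled mismatch/bulge patterns and an
NGG/NAG PAM; a larger set of uncleaved "decoy" sites similar enough to be
recovered by negative mining; and per-study read counts whose intensities
follow a logistic function of alignment score (plus weaker GC and enthalpy
effects) with Gaussian noise on the log scale.

Study scales mirror the real heterogeneity: the reference study reports
noisy log counts directly, while each additional study reports counts on
its own linear scale (``reference = slope * study + intercept``), which the
harmonization module must invert.  Measurement noise is attached to the
reference assay; the ground-truth (slope, intercept) of every other study
is therefore exactly recoverable by ordinary least squares, up to sampling
error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import gc_fraction, reverse_complement
from .align import AlignmentParams, DEFAULT_PARAMS, GuideRNA, TargetSite, extract_flanks
from .thermo import nn_enthalpy


@dataclass(frozen=True)
class StudySpec:
    """One simulated assay: its scale relative to the reference and depth."""

    name: str
    slope: float = 1.0
    intercept: float = 0.0
    #: fraction of guides this study profiles (guides are taken in order)
    coverage: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic fixture generator.

    Defaults emulate the assembled multi-study compendium at desk scale:
    human-like GC, a few hundred cleaved sites over a handful of guides,
    ~3 mismatches per off-target on average with bulges in roughly a fifth
    of sites, NGG dominating NAG, and log-scale read noise.
    """

    genome_length: int = 300_000
    gc_fraction: float = 0.41
    n_guides: int = 5
    cleaved_per_guide: int = 100
    decoys_per_guide: int = 250
    #: probability of k mismatches (k = index) in a planted cleaved site
    mismatch_probs: tuple[float, ...] = (0.04, 0.09, 0.16, 0.24, 0.24, 0.15, 0.08)
    #: probability that a planted cleaved site carries one bulge
    bulge_prob: float = 0.18
    #: decoys carry 3..5 mismatches: above the mining threshold yet below
    #: the typical cleaved site, so the two classes overlap realistically
    decoy_mismatch_range: tuple[int, int] = (3, 5)
    pam_ngg_prob: float = 0.9
    #: logistic effect model on the latent cleavage intensity
    effect_align: float = 2.5
    effect_gc: float = 0.3
    effect_enthalpy: float = 0.3
    effect_intercept: float = 0.0
    #: peak log10 read count on the reference scale
    max_log_reads: float = 3.5
    #: detection floor: cleaved sites emit at least this fraction of the
    #: peak log count (assays only report sites they could detect)
    intensity_floor: float = 0.2
    noise_sd: float = 0.25
    studies: tuple[StudySpec, ...] = (
        StudySpec("SimRef", 1.0, 0.0, 1.0),
        StudySpec("SimAlt", 0.8, 0.5, 0.6),
    )
    master_seed: int = 20170

    def __post_init__(self):
        if not math.isclose(sum(self.mismatch_probs), 1.0, abs_tol=1e-9):
            raise ValueError("mismatch_probs must sum to 1")
        for p in (self.gc_fraction, self.bulge_prob, self.pam_ngg_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """An i.i.d. random contig at the configured GC fraction."""
    rng = rng if rng is not None else np.random.default_rng(config.master_seed)
    p_gc = config.gc_fraction / 2.0
    p_at = (1.0 - config.gc_fraction) / 2.0
    bases = rng.choice(list("ACGT"), size=config.genome_length, p=[p_at, p_gc, p_gc, p_at])
    return {"sim1": "".join(bases)}


def _mutate(spacer: str, n_mismatch: int, with_bulge: bool, rng) -> str:
    """A genomic sequence that aligns to the spacer with the planted edits."""
    seq = list(spacer)
    if n_mismatch:
        for i in rng.choice(len(seq), size=n_mismatch, replace=False):
            seq[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    if with_bulge:
        # DNA bulge: extra base in the genome; RNA bulge: missing base.
        # Interior positions only: an indel at the PAM-distal edge is
        # indistinguishable from a window shift and needs no gap to explain.
        pos = int(rng.integers(2, len(seq) - 2))
        if rng.random() < 0.5:
            seq.insert(pos, rng.choice(list("ACGT")))
        else:
            del seq[pos]
    return "".join(seq)


def plant_targets(
    genome: dict[str, str],
    guide: GuideRNA,
    config: SimConfig,
    rng: np.random.Generator,
    max_retries: int = 200,
    occupied: list[tuple[int, int]] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert one on-target, cleaved off-targets, and uncleaved decoys.

    Returns the edited genome and a truth table (one row per planted site)
    with the planted mismatch/bulge counts and the ``label`` column.
    Planted sites never overlap each other (bounded retries, then error);
    pass a shared ``occupied`` list when planting several guides into the
    same genome.
    """
    seq_id, seq = next(iter(genome.items()))
    chars = list(seq)
    occupied = occupied if occupied is not None else []
    rows = []

    def _place(site_seq: str, pam: str, label: str, n_mm: int, bulged: bool):
        block_fwd_len = len(site_seq) + 3
        for _ in range(max_retries):
            strand = "+" if rng.random() < 0.5 else "-"
            p = int(rng.integers(120, len(chars) - block_fwd_len - 120))
            if any(p < e + 12 and p + block_fwd_len + 12 > s for (s, e) in occupied):
                continue
            if strand == "+":
                block = site_seq + pam
                start, end = p, p + len(site_seq)
            else:
                block = reverse_complement(site_seq + pam)
                start, end = p + 3, p + 3 + len(site_seq)
            chars[p : p + block_fwd_len] = block
            occupied.append((p, p + block_fwd_len))
            rows.append(
                {
                    "guide_id": guide.id,
                    "chrom": seq_id,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "site_seq": site_seq,
                    "pam": pam,
                    "label": label,
                    "planted_mismatches": n_mm,
                    "planted_bulge": bulged,
                }
            )
            return
        raise RuntimeError("could not place a planted site without collision")

    def _pam():
        return ("A" if rng.random() < 0.5 else "T") + (
            "GG" if rng.random() < config.pam_ngg_prob else "AG"
        )

    _place(guide.spacer, _pam()[0] + "GG", "cleaved", 0, False)  # on-target, NGG
    mm_counts = rng.choice(
        len(config.mismatch_probs), size=config.cleaved_per_guide - 1, p=config.mismatch_probs
    )
    for n_mm in mm_counts:
        bulged = bool(rng.random() < config.bulge_prob)
        _place(_mutate(guide.spacer, int(n_mm), bulged, rng), _pam(), "cleaved", int(n_mm), bulged)
    lo, hi = config.decoy_mismatch_range
    for _ in range(config.decoys_per_guide):
        n_mm = int(rng.integers(lo, hi + 1))
        _place(_mutate(guide.spacer, n_mm, False, rng), _pam(), "uncleaved", n_mm, False)

    genome = {seq_id: "".join(chars)}
    return genome, pd.DataFrame(rows)


def _latent_intensity(truth: pd.DataFrame, genome: dict[str, str], config: SimConfig) -> np.ndarray:
    """Logistic effect model on alignment score, site GC, and enthalpy.

    A stand-in for the unknown biological response: scores map through a
    logistic so intensities saturate at the on-target.
    """
    from .align import best_window_scores

    sites = [site_from_row(row, genome) for _, row in truth.iterrows()]
    scores = best_window_scores(GuideRNA(truth["guide_id"].iloc[0], truth["guide_seq"].iloc[0]),
                                sites, DEFAULT_PARAMS)
    gc = np.array([gc_fraction(s.site_seq) for s in sites])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enth = np.array(
            [nn_enthalpy(s.upstream_flank + s.site_seq + s.pam + s.downstream_flank) for s in sites]
        )
    z_score = (scores - 17.5) / 2.5  # -1 near the mining threshold, +1 at perfect
    z_gc = gc - 0.5
    z_enth = (enth - enth.mean()) / (enth.std() + 1e-9)
    lin = (
        config.effect_intercept
        + config.effect_align * z_score
        + config.effect_gc * z_gc
        + config.effect_enthalpy * (-np.abs(z_enth))  # extremes depressed
    )
    return 1.0 / (1.0 + np.exp(-lin))


def site_from_row(row, genome: dict[str, str], flank: int = 100) -> TargetSite:
    """Materialize a TargetSite (with flanks) from a truth/record row."""
    up, down = extract_flanks(genome, row["chrom"], int(row["start"]), int(row["end"]),
                              row["strand"], flank=flank)
    return TargetSite(
        row["chrom"], int(row["start"]), int(row["end"]), row["strand"],
        row["site_seq"], row["pam"], upstream_flank=up, downstream_flank=down,
    )


def simulate_reads(
    truth: pd.DataFrame,
    genome: dict[str, str],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-study read counts for planted sites.

    The reference-scale log intensity of a cleaved site is
    ``max_log_reads * latent``; the reference study observes it plus
    Gaussian noise, while every other study reports
    ``(intensity - intercept) / slope`` exponentiated and rounded at its
    own scale.  Uncleaved sites emit zero reads everywhere.
    """
    parts = []
    for gid, sub in truth.groupby("guide_id", sort=True):
        sub = sub.reset_index(drop=True)
        latent = _latent_intensity(sub, genome, config)
        floor = config.intensity_floor
        y_site = config.max_log_reads * (floor + (1.0 - floor) * latent)
        for k, spec in enumerate(config.studies):
            n_profiled = max(1, int(round(spec.coverage * config.n_guides)))
            gid_index = sorted(truth["guide_id"].unique()).index(gid)
            if gid_index >= n_profiled:
                continue
            block = sub.copy()
            block["study"] = spec.name
            if k == 0:
                y_obs = y_site + rng.normal(0.0, config.noise_sd, size=len(block))
            else:
                y_obs = (y_site - spec.intercept) / spec.slope
            reads = np.round(np.power(10.0, np.clip(y_obs, 0.0, None)) - 1.0).astype(int)
            cleaved = block["label"].values == "cleaved"
            reads = np.where(cleaved, np.maximum(reads, 1), 0)
            block["raw_reads"] = reads
            parts.append(block)
    return pd.concat(parts, ignore_index=True)


@dataclass
class SimulatedData:
    genome: dict[str, str]
    guides: list[GuideRNA]
    records: pd.DataFrame  # per-study records incl. raw_reads and label
    truth: pd.DataFrame    # one row per planted site with ground-truth edits
    config: SimConfig


def simulate_dataset(config: SimConfig | None = None, seed: int | None = None) -> SimulatedData:
    """End-to-end fixture: genome, guides, planted sites, multi-study reads."""
    config = config if config is not None else SimConfig()
    if seed is not None:
        config = replace(config, master_seed=int(seed))
    rng = np.random.default_rng(config.master_seed)
    genome = simulate_genome(config, rng)
    guides = []
    truths = []
    occupied: list[tuple[int, int]] = []
    for i in range(config.n_guides):
        spacer = "G" + "".join(rng.choice(list("ACGT"), size=19))
        g = GuideRNA(f"guide{i + 1:02d}", spacer)
        guides.append(g)
        genome, truth = plant_targets(genome, g, config, rng, occupied=occupied)
        truth["guide_seq"] = g.spacer
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    records = simulate_reads(truth, genome, config, rng)
    return SimulatedData(genome, guides, records, truth, config)
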