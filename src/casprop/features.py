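"""Feature engineering for (guide, site, alignment) triples.

Features fall into three families: similarity between the sgRNA and the
site (alignment score, mismatch/bulge counts and positions, mismatch
chemistry), properties of the genomic site itself (PAM type, nucleotide
identities at informative positions, GC content, duplex enthalpy, DNA-shape
descriptors, chromatin annotations), and properties of the sgRNA (folding
energy, via a pluggable provider).

Mismatch chemistry is read in the RNA:DNA heteroduplex: the guide (RNA)
base faces the complement of the protospacer-sense base.  A wobble is
rG.dT or rU.dG (guide base listed first); otherwise purine-purine and
pyrimidine-pyrimidine pairs are the two transition classes and anything
else is a transversion.

Pluggable inputs that are absent (shape lookup tables, annotations, folding
energies) yield NaN — explicitly null-flagged, never silently zero; the
model layer imputes them with a companion missingness indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import complement, gc_fraction
from .align import SPACER_LENGTH, GuideRNA, GuideTargetAlignment, TargetSite
from .thermo import nn_enthalpy

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

WOBBLE = "wobble"
TRANSITION_RR = "transition_RR"
TRANSITION_YY = "transition_YY"
TRANSVERSION = "transversion"
MISMATCH_CLASSES = (WOBBLE, TRANSITION_RR, TRANSITION_YY, TRANSVERSION)

FLANK_WINDOW = 100  # nt of flank entering GC / enthalpy windows
ENTHALPY_TARGET_SPAN = 23  # 20-nt site + 3-nt PAM


def classify_mismatch(guide_base: str, opposing_target_base: str) -> str:
    """Class of a heteroduplex mismatch (guide RNA base vs target-strand base).

    The pair must actually mismatch: called on a Watson-Crick pair it
    raises.  Wobble pairs (rG.dT, rU.dG) take precedence over the
    purine/pyrimidine classification.
    """
    g = guide_base.upper().replace("U", "T")
    t = opposing_target_base.upper()
    if t == complement(g):
        raise ValueError(f"{guide_base}/{opposing_target_base} is a matched pair")
    if (g, t) in (("G", "T"), ("T", "G")):
        return WOBBLE
    if g in PURINES and t in PURINES:
        return TRANSITION_RR
    if g in PYRIMIDINES and t in PYRIMIDINES:
        return TRANSITION_YY
    return TRANSVERSION


@dataclass
class AnnotationTable:
    """Interval-keyed genomic annotations (half-open coordinates).

    ``table`` columns: seq_id, start, end, and any of dnase_hs,
    exon_strand, cpg, expression.  Lookup is by interval overlap with the
    protospacer window.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"seq_id", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if "expression" in self.table.columns and (self.table["expression"].dropna() < 0).any():
            raise ValueError("expression values must be non-negative")

    def lookup(self, seq_id: str, start: int, end: int) -> pd.DataFrame:
        t = self.table
        hit = (t["seq_id"] == seq_id) & (t["start"] < end) & (t["end"] > start)
        return t[hit]


@dataclass
class ShapeTables:
    """k-mer lookup tables for DNA-shape descriptors.

    ``mgw`` maps pentamers to minor groove width (angstrom); ``stiffness``
    maps dinucleotides to a bending-stiffness score.  Either may be None.
    """

    mgw: Mapping[str, float] | None = None
    stiffness: Mapping[str, float] | None = None


def _kmer_mean(seq: str, table: Mapping[str, float], k: int) -> float:
    vals = [table[seq[i : i + k]] for i in range(len(seq) - k + 1) if seq[i : i + k] in table]
    return float(np.mean(vals)) if vals else float("nan")


def window20(site: TargetSite) -> str:
    """The 20-nt PAM-anchored window (borrowing flank if the site is short)."""
    ext = site.upstream_flank + site.site_seq
    if len(ext) < SPACER_LENGTH:
        return ext
    return ext[-SPACER_LENGTH:]


def compute_features(
    guide: GuideRNA,
    site: TargetSite,
    aln: GuideTargetAlignment,
    annotations: AnnotationTable | None = None,
    shape_tables: ShapeTables | None = None,
    folding_provider: Callable[[GuideRNA], float] | None = None,
    extra: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """The named numeric feature vector for one (guide, site, alignment).

    Deterministic and pure; pluggable features missing their inputs are
    NaN.  ``extra`` columns (e.g. externally supplied scores) pass through
    unchanged.
    """
    fv: dict[str, float] = {}
    # --- similarity ---
    fv["alignment_score"] = aln.score
    fv["n_match"] = aln.n_match
    fv["n_mismatch"] = aln.n_mismatch
    fv["n_dna_bulge"] = aln.n_dna_bulge
    fv["n_rna_bulge"] = aln.n_rna_bulge
    fv["n_bulges"] = aln.n_bulges
    fv["chosen_window"] = aln.chosen_window
    mm_pos = set(aln.mismatch_positions)
    for p in range(1, SPACER_LENGTH + 1):
        fv[f"mm_pos_{p:02d}"] = float(p in mm_pos)
    fv["mm_pos_mean"] = float(np.mean(aln.mismatch_positions)) if mm_pos else 0.0
    counts = dict.fromkeys(MISMATCH_CLASSES, 0)
    for gb, tb in aln.mismatch_pairs:
        counts[classify_mismatch(gb, tb)] += 1
    for cls in MISMATCH_CLASSES:
        fv[f"n_{cls}"] = counts[cls]
    bp = aln.bulge_positions()
    fv["bulge_pos_mean"] = float(np.mean(bp)) if bp else 0.0
    # --- PAM ---
    for pt in ("NGG", "NAG", "other"):
        fv[f"pam_{pt}"] = float(site.pam_type == pt)
    # --- nucleotide identities (site sense) ---
    w20 = window20(site)
    down = site.downstream_flank
    for pos in (2, 4, 5, 20):
        base = w20[-pos] if len(w20) >= pos else None
        for nt in "ACGT":
            fv[f"pos{pos}_{nt}"] = float(base == nt) if base else float("nan")
    for k in range(1, 6):
        base = down[k - 1] if len(down) >= k else None
        for nt in "ACGT":
            fv[f"pamdown{k}_{nt}"] = float(base == nt) if base else float("nan")
    # --- composition & thermodynamics ---
    fv["gc_site"] = gc_fraction(w20)
    up100 = site.upstream_flank[-FLANK_WINDOW:]
    down100 = down[:FLANK_WINDOW]
    fv["gc_flank_up"] = gc_fraction(up100)
    fv["gc_flank_down"] = gc_fraction(down100)
    fv["dna_enthalpy"] = nn_enthalpy(up100 + w20 + site.pam + down100)
    # --- DNA shape (pluggable lookups) ---
    mgw_region = (w20[-1:] if w20 else "") + site.pam + down[:2]
    if shape_tables is not None and shape_tables.mgw is not None:
        fv["mgw_pam"] = _kmer_mean(mgw_region, shape_tables.mgw, 5)
    else:
        fv["mgw_pam"] = float("nan")
    if shape_tables is not None and shape_tables.stiffness is not None:
        fv["bending_stiffness"] = _kmer_mean(w20, shape_tables.stiffness, 2)
    else:
        fv["bending_stiffness"] = float("nan")
    # --- genomic annotations ---
    if annotations is not None:
        hits = annotations.lookup(site.seq_id, site.start, site.end)
        fv["dnase_hs"] = float(bool(hits.get("dnase_hs", pd.Series(dtype=float)).fillna(0).astype(bool).any()))
        exon_strands = set(hits.get("exon_strand", pd.Series(dtype=object)).dropna())
        fv["exon_coding"] = float(site.strand in exon_strands)
        fv["exon_opposite"] = float(bool(exon_strands - {site.strand}))
        fv["cpg_island"] = float(bool(hits.get("cpg", pd.Series(dtype=float)).fillna(0).astype(bool).any()))
        expr = hits.get("expression", pd.Series(dtype=float)).dropna()
        fv["expression"] = float(expr.max()) if len(expr) else 0.0
    else:
        for name in ("dnase_hs", "exon_coding", "exon_opposite", "cpg_island", "expression"):
            fv[name] = float("nan")
    # --- sgRNA thermodynamics ---
    fv["sgrna_folding_energy"] = (
        float(folding_provider(guide)) if folding_provider is not None else float("nan")
    )
    if extra:
        for k, v in extra.items():
            fv[str(k)] = float(v)
    return fv


def feature_names() -> list[str]:
    """Canonical registry order of the built-in features."""
    dummy_guide = GuideRNA("_", "A" * 20)
    dummy_site = TargetSite("_", 0, 20, "+", "A" * 20, "AGG")
    from .align import align_fixed

    aln = align_fixed(dummy_guide.spacer, "A" * 20)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return list(compute_features(dummy_guide, dummy_site, aln))


def features_to_frame(vectors: Sequence[Mapping[str, float]]) -> pd.DataFrame:
    """Stack feature dicts into a DataFrame in registry order (extras last)."""
    df = pd.DataFrame(list(vectors))
    registry = [c for c in feature_names() if c in df.columns]
    extras = [c for c in df.columns if c not in registry]
    return df[registry + extras]
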