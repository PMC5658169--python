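"""Re-analysis of externally supplied per-site data tables.

These routines reproduce headline statistics from the assembled multi-study
off-target compendium when its per-site tables are supplied by the user
(published experimental data, not bundled here): the effect of allowing
bulges on realignment statistics, and guide-level cross-validated benchmark
metrics over a feature/frequency table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .align import (
    AlignmentParams,
    GuideRNA,
    TargetSite,
    align_best_window_many,
)
from .dataset import TrainingDataset, round_seeds, sample_round
from .ensemble import EnsembleConfig, predict, train
from .evaluate import metric_suite, per_guide_metrics

GAPPED = AlignmentParams(1.0, 0.0, -1.25, 3)
GAPLESS = AlignmentParams(1.0, 0.0, -1.25, 0)

FREQ_CANDIDATES = ("target_value", "harmonized", "frequency", "raw_reads")


def _frequency_column(table: pd.DataFrame) -> str:
    for c in FREQ_CANDIDATES:
        if c in table.columns:
            return c
    raise ValueError(f"no cleavage-frequency column among {FREQ_CANDIDATES}")


def _sites(sub: pd.DataFrame) -> list[TargetSite]:
    sites = []
    for i, row in enumerate(sub.itertuples()):
        seq = str(row.site_seq).upper()
        up = str(getattr(row, "upstream_flank", "") or "")
        window = seq[-20:] if len(seq) > 20 else seq
        up = up + seq[:-20] if len(seq) > 20 else up
        pam = str(getattr(row, "pam", "") or "AGG")
        start = int(getattr(row, "start", i * 100))
        sites.append(TargetSite(
            str(getattr(row, "chrom", "?")), start, start + len(window),
            str(getattr(row, "strand", "+")), window, pam, upstream_flank=up))
    return sites


def realignment_statistics(table: pd.DataFrame) -> dict:
    """Bulge-aware realignment of an assembled per-site table.

    Requires guide_id, guide_seq, site_seq (PAM-proximal end last, extra
    5' context welcome) and a cleavage-frequency column.  Returns counts of
    bulged sites, mean mismatches/matches, and the per-guide-averaged r^2
    between alignment score and frequency with and without gaps.
    """
    freq_col = _frequency_column(table)
    n_sites = 0
    n_bulged = 0
    bulges_in_bulged = []
    mism, match = [], []
    r2_gap, r2_nogap = [], []
    for gid, sub in table.groupby("guide_id", sort=True):
        guide = GuideRNA(str(gid), sub["guide_seq"].iloc[0])
        sites = _sites(sub)
        gapped = align_best_window_many(guide, sites, GAPPED)
        # gapless baseline needs a full 20-nt window; sites without enough
        # sequence context drop out of that comparison only
        full = [k for k, s in enumerate(sites)
                if len(s.upstream_flank) + len(s.site_seq) >= 20]
        gapless = [None] * len(sites)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for k, a in zip(full, align_best_window_many(
                    guide, [sites[k] for k in full], GAPLESS)):
                gapless[k] = a
        n_sites += len(sites)
        for a in gapped:
            if a.n_bulges:
                n_bulged += 1
                bulges_in_bulged.append(a.n_bulges)
            mism.append(a.n_mismatch)
            match.append(a.n_match)
        freqs = sub[freq_col].astype(float).values
        keep = np.array([a.n_mismatch > 0 or a.n_bulges > 0 for a in gapped])
        if keep.sum() >= 2 and len(set(freqs[keep])) > 1:
            for alns, bucket in ((gapped, r2_gap), (gapless, r2_nogap)):
                s = np.array([a.score if a is not None else np.nan for a in alns])[keep]
                f = freqs[keep][~np.isnan(s)]
                s = s[~np.isnan(s)]
                if len(s) >= 2 and len(set(s)) > 1 and len(set(f)) > 1:
                    r, _ = stats.pearsonr(s, f)
                    bucket.append(r * r)
    return {
        "n_sites": n_sites,
        "n_sites_with_bulges": n_bulged,
        "mean_bulges_in_bulged": float(np.mean(bulges_in_bulged)) if bulges_in_bulged else 0.0,
        "mean_mismatches": float(np.mean(mism)),
        "mean_matches": float(np.mean(match)),
        "mean_r2_with_gaps": float(np.mean(r2_gap)) if r2_gap else np.nan,
        "mean_r2_without_gaps": float(np.mean(r2_nogap)) if r2_nogap else np.nan,
    }


NON_FEATURE = {"guide_id", "study", "chrom", "start", "end", "raw_reads",
               "target_value", "harmonized", "frequency", "label",
               "predicted", "cctop_score", "optcd_score", "cfd_score"}


def benchmark_from_prediction_table(
    table: pd.DataFrame,
    config: EnsembleConfig | None = None,
    master_seed: int = 0,
) -> dict:
    """Guide-level cross-validated benchmark over a feature table.

    Requires guide_id, label, a frequency column, numeric feature columns,
    and (optionally) a cfd_score column for the deterministic external
    comparison.  Re-trains the balanced ensemble per held-out guide on the
    supplied features and reports pooled/per-guide metrics.
    """
    config = config or EnsembleConfig()
    freq_col = _frequency_column(table)
    df = table.reset_index(drop=True).copy()
    df["target_value"] = df[freq_col].astype(float)
    feature_cols = [c for c in df.select_dtypes(include=[np.number]).columns
                    if c not in NON_FEATURE]
    if not feature_cols:
        raise ValueError("no numeric feature columns found")
    pos = df[df["label"] == "cleaved"]
    neg = df[df["label"] != "cleaved"]
    dataset = TrainingDataset(pos, neg)
    parts = []
    for gid in dataset.guides():
        tr_pos = pos[pos["guide_id"] != gid]
        tr_neg = neg[neg["guide_id"] != gid]
        te = df[df["guide_id"] == gid]
        sampled = [sample_round(TrainingDataset(tr_pos, tr_neg), s)
                   for s in round_seeds(master_seed, config.n_rounds)]
        tr_idx = tr_pos.index.union(tr_neg.index)
        model = train(sampled, df.loc[tr_idx, feature_cols],
                      df.loc[tr_idx, "target_value"], config=config)
        scores = predict(model, te[feature_cols])["score"]
        parts.append(pd.DataFrame({
            "guide_id": gid, "label": te["label"],
            "observed": te["target_value"], "predicted": scores,
        }, index=te.index))
    predictions = pd.concat(parts)
    pooled = metric_suite(predictions["observed"], predictions["predicted"],
                          predictions["label"])
    per_guide = per_guide_metrics(predictions)
    out = {
        "pooled_r2": pooled["pearson_r2"],
        "roc_auc": pooled["roc_auc"],
        "prc_auc": pooled["prc_auc"],
        "per_guide_mean_r2": float(per_guide["pearson_r2"].dropna().astype(float).mean()),
    }
    if "cfd_score" in df.columns:
        sub = df.dropna(subset=["cfd_score"])
        r, _ = stats.pearsonr(sub["target_value"], sub["cfd_score"].astype(float))
        out["cfd_pooled_r2"] = float(r * r)
    return out
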