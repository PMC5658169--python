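"""Cross-validation protocols and the metric suite.

Two protocols probe different generalization questions.  Leave-one-sgRNA-out
holds out every record of one guide per fold — including a per-fold
re-optimization of the alignment parameters on the training guides only,
after which alignment-derived features are recomputed for train and test —
and asks whether cleavage propensity transfers to unseen guides.
Leave-study-out holds out a whole assay and, because some guides were
profiled by several studies, reports metrics separately for guides unique
to the held-out study and guides it shares with the training data.

Test sets pair each guide's held-out cleaved sites with an equal-sized
random sample of its uncleaved sites, drawn once per fold with the fold
seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .align import AlignmentParams, DEFAULT_PARAMS, GuideRNA, optimize_params
from .dataset import TrainingDataset, deduplicate, round_seeds, sample_round
from .ensemble import EnsembleConfig, predict, train
from .harmonize import finalize_targets, harmonize_studies
from .pipeline import feature_table, sites_from_records


# ---------------------------------------------------------------------------
# metrics


def metric_suite(observed, predicted, labels=None) -> dict:
    """Pearson r^2, Spearman rho, ROC-AUC, PRC-AUC (trapezoidal), RMSE.

    ``labels`` is the binary cleaved/uncleaved vector for the AUCs; when
    omitted, AUCs are computed against ``observed > 0``.  Degenerate inputs
    (constant predictions, single-class labels) yield None entries with a
    warning rather than an exception.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 2:
        raise ValueError("need at least two points")
    y = (np.asarray(labels) == "cleaved") if labels is not None else (obs > 0)
    out: dict[str, float | None] = {}
    if np.allclose(pred, pred[0]) or np.allclose(obs, obs[0]):
        warnings.warn("constant observed or predicted values: correlation undefined",
                      stacklevel=2)
        out["pearson_r2"] = None
        out["spearman_rho"] = None
    else:
        r, _ = stats.pearsonr(obs, pred)
        out["pearson_r2"] = float(r * r)
        out["spearman_rho"] = float(stats.spearmanr(obs, pred).statistic)
    if y.all() or not y.any():
        warnings.warn("single-class labels: AUCs undefined", stacklevel=2)
        out["roc_auc"] = None
        out["prc_auc"] = None
    else:
        out["roc_auc"] = float(skm.roc_auc_score(y, pred))
        prec, rec, _ = skm.precision_recall_curve(y, pred)
        out["prc_auc"] = float(skm.auc(rec, prec))
    out["rmse"] = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return out


def per_guide_metrics(predictions: pd.DataFrame) -> pd.DataFrame:
    """Metric suite per guide over a fold-prediction table."""
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gid, sub in predictions.groupby("guide_id", sort=True):
            rows[gid] = metric_suite(sub["observed"], sub["predicted"], sub["label"])
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# fold machinery


@dataclass
class CVConfig:
    """Knobs for the cross-validation protocols."""

    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    alignment_params: AlignmentParams = DEFAULT_PARAMS
    #: per-fold alignment-parameter re-optimization (guide-level CV only)
    reoptimize_params: bool = True
    param_grid: Sequence[AlignmentParams] | None = None
    master_seed: int = 0


@dataclass
class EvaluationReport:
    """Predictions plus pooled / per-guide metric summaries."""

    predictions: pd.DataFrame  # guide_id, study, label, observed, predicted
    pooled: dict
    per_guide: pd.DataFrame
    fold_params: dict = field(default_factory=dict)
    splits: dict = field(default_factory=dict)  # study mode: unique/common metrics

    def per_guide_mean(self, metric: str = "pearson_r2") -> tuple[float, float]:
        vals = self.per_guide[metric].dropna().astype(float)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def _fold_seed(master_seed: int, tag: str) -> int:
    h = zlib.crc32(tag.encode())  # stable across processes, unlike hash()
    return int(
        np.random.SeedSequence([int(master_seed), h]).generate_state(1)[0] % (2**31)
    )


def _train_and_predict(train_pos, train_neg, test_records, genome, params, config,
                       annotations=None, shape_tables=None):
    all_records = pd.concat([train_pos, train_neg, test_records])
    feats = feature_table(all_records, genome, params,
                          annotations=annotations, shape_tables=shape_tables)
    targets = all_records["target_value"].astype(float)
    fold_data = TrainingDataset(positives=train_pos, negatives=train_neg)
    seeds = round_seeds(config.ensemble.master_seed, config.ensemble.n_rounds)
    sampled = [sample_round(fold_data, s) for s in seeds]
    train_idx = train_pos.index.union(train_neg.index)
    model = train(sampled, feats.loc[train_idx], targets.loc[train_idx],
                  config=config.ensemble, alignment_params=params)
    preds = predict(model, feats.loc[test_records.index])
    return preds["score"]


def _optimization_records(positives: pd.DataFrame, genome) -> list:
    recs = []
    for gid, sub in positives.groupby("guide_id", sort=True):
        guide = GuideRNA(gid, sub["guide_seq"].iloc[0])
        sites = sites_from_records(sub, genome)
        for site, tv in zip(sites, sub["target_value"]):
            recs.append((guide, site, float(tv)))
    return recs


def loso_cv(dataset: TrainingDataset, genome: Mapping[str, str],
            config: CVConfig | None = None, annotations=None,
            shape_tables=None) -> EvaluationReport:
    """Leave-one-sgRNA-out cross-validation.

    Per fold: re-optimize alignment parameters on the training guides,
    recompute alignment features for train and test, draw the balanced
    training rounds, train the ensemble, and score the held-out guide's
    cleaved sites plus an equal-sized random draw of its uncleaved sites.
    """
    config = config or CVConfig()
    guides = dataset.guides()
    if len(guides) < 2:
        raise ValueError("leave-one-sgRNA-out needs at least two guides")
    pred_parts = []
    fold_params = {}
    for gid in guides:
        train_pos = dataset.positives[dataset.positives["guide_id"] != gid]
        train_neg = dataset.negatives[dataset.negatives["guide_id"] != gid]
        test_pos = dataset.positives[dataset.positives["guide_id"] == gid]
        neg_pool = dataset.negatives[dataset.negatives["guide_id"] == gid]
        fseed = _fold_seed(config.master_seed, f"loso:{gid}")
        test_neg = neg_pool.sample(n=min(len(test_pos), len(neg_pool)),
                                   random_state=fseed)
        if config.reoptimize_params:
            params = optimize_params(_optimization_records(train_pos, genome),
                                     grid=config.param_grid)
        else:
            params = config.alignment_params
        fold_params[gid] = params
        test_records = pd.concat([test_pos, test_neg])
        # protocol audit: the held-out guide contributes nothing to training
        assert not set(test_records.index) & (set(train_pos.index) | set(train_neg.index))
        assert (train_pos["guide_id"] != gid).all()
        scores = _train_and_predict(train_pos, train_neg, test_records, genome,
                                    params, config, annotations, shape_tables)
        pred_parts.append(pd.DataFrame({
            "guide_id": gid,
            "study": test_records.get("study", "?"),
            "label": test_records["label"],
            "observed": test_records["target_value"].astype(float),
            "predicted": scores,
        }, index=test_records.index))
    predictions = pd.concat(pred_parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = metric_suite(predictions["observed"], predictions["predicted"],
                              predictions["label"])
    return EvaluationReport(predictions, pooled, per_guide_metrics(predictions),
                            fold_params=fold_params)


def leave_study_out(cleaved_records: pd.DataFrame, negatives: pd.DataFrame,
                    genome: Mapping[str, str], reference_study: str,
                    config: CVConfig | None = None) -> EvaluationReport:
    """Leave-study-out cross-validation with a unique/common guide split.

    ``cleaved_records`` is the pre-deduplication multi-study table (so a
    guide profiled twice appears under both studies); training folds are
    deduplicated after removing the held-out study.  Alignment parameters
    are not re-optimized per fold in this protocol.
    """
    config = config or CVConfig()
    cleaved = cleaved_records[cleaved_records["label"] == "cleaved"]
    studies = sorted(set(cleaved["study"]))
    if len(studies) < 2:
        raise ValueError("leave-study-out needs at least two studies")
    harmonized, _ = harmonize_studies(cleaved, reference_study=reference_study)
    scaled = finalize_targets(harmonized).reset_index(drop=True)
    # record ids must not collide with the negative table's
    offset = (int(negatives.index.max()) + 1) if len(negatives) else 0
    scaled.index = scaled.index + offset
    study_guides = cleaved.groupby("guide_id")["study"].nunique()
    common = set(study_guides[study_guides >= 2].index)

    pred_parts = []
    splits: dict[str, dict] = {}
    for study in studies:
        held = scaled[scaled["study"] == study]
        if held.empty:
            warnings.warn(f"study {study!r} has no cleaved records; skipped")
            continue
        train_cleaved = scaled[scaled["study"] != study]
        ref = reference_study if reference_study != study else studies[0]
        if ref == study:  # reference itself held out: fall back to largest study
            sizes = train_cleaved.groupby("study").size().sort_values(ascending=False)
            ref = str(sizes.index[0])
        train_pos = deduplicate(train_cleaved, reference_study=ref)
        train_gids = set(train_pos["guide_id"])
        train_neg = negatives[negatives["guide_id"].isin(train_gids)]
        test_parts = []
        for gid, sub in held.groupby("guide_id", sort=True):
            pool = negatives[negatives["guide_id"] == gid]
            fseed = _fold_seed(config.master_seed, f"study:{study}:{gid}")
            test_parts.append(sub)
            test_parts.append(pool.sample(n=min(len(sub), len(pool)),
                                          random_state=fseed))
        test_records = pd.concat(test_parts)
        # negatives reused in training are dropped from this fold's test set
        test_records = test_records[~test_records.index.isin(
            train_neg.index.intersection(test_records.index))]
        scores = _train_and_predict(train_pos, train_neg, test_records, genome,
                                    config.alignment_params, config)
        fold = pd.DataFrame({
            "guide_id": test_records["guide_id"],
            "study": study,
            "label": test_records["label"],
            "observed": test_records["target_value"].astype(float),
            "predicted": scores,
        }, index=test_records.index)
        pred_parts.append(fold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splits[study] = {
                "all": metric_suite(fold["observed"], fold["predicted"], fold["label"]),
            }
            for name, mask in (("common", fold["guide_id"].isin(common)),
                               ("unique", ~fold["guide_id"].isin(common))):
                sub = fold[mask]
                if len(sub) >= 2:
                    splits[study][name] = metric_suite(sub["observed"], sub["predicted"],
                                                       sub["label"])
    predictions = pd.concat(pred_parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = metric_suite(predictions["observed"], predictions["predicted"],
                              predictions["label"])
    return EvaluationReport(predictions, pooled, per_guide_metrics(predictions),
                            splits=splits)


def negative_fraction_sweep(report: EvaluationReport,
                            fractions: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.0),
                            seed: int = 0) -> pd.DataFrame:
    """Per-guide averaged r^2 as the uncleaved test sample shrinks.

    Fraction 1.0 reproduces the headline per-guide average; 0.0 keeps the
    cleaved sites only.
    """
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"fraction {f} outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    preds = report.predictions
    for f in fractions:
        r2s = []
        for gid, sub in preds.groupby("guide_id", sort=True):
            pos = sub[sub["label"] == "cleaved"]
            neg = sub[sub["label"] != "cleaved"]
            k = int(round(f * len(neg)))
            take = neg.sample(n=k, random_state=int(rng.integers(2**31))) if k else neg.iloc[0:0]
            both = pd.concat([pos, take])
            if len(both) < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metric_suite(both["observed"], both["predicted"], both["label"])
            if m["pearson_r2"] is not None:
                r2s.append(m["pearson_r2"])
        rows.append({"fraction": f, "mean_r2": float(np.mean(r2s)) if r2s else np.nan,
                     "n_guides": len(r2s)})
    return pd.DataFrame(rows)
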