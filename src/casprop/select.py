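"""Feature selection, importance extraction, and mechanism-probing tests.

Forward selection greedily grows a feature set under guide-level
cross-validation: at each step the candidate that raises the pooled Pearson
r^2 of held-out predictions the most is adjoined (15 iterations by
default), after which a forest fitted on the selected set yields relative
importances.  Because a full-budget cross-validation per candidate per step
is quadratic, candidates are screened with a reduced-cost configuration
(fewer rounds/trees, no per-fold alignment re-optimization), exposed in
:class:`SelectionConfig`.

Two statistical probes of the cleavage mechanism are included: a
chi-square contingency test for enrichment of wobble mismatches as the
total mismatch count grows, and a permutation test asking whether sites in
the extreme tails of the duplex-enthalpy distribution are cleaved at lower
frequencies than mid-range sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentParams, DEFAULT_PARAMS, GuideTargetAlignment
from .dataset import TrainingDataset, round_seeds, sample_round
from .ensemble import EnsembleConfig, MISSING_SUFFIX, predict, train
from .evaluate import _fold_seed, metric_suite
from .features import WOBBLE, classify_mismatch
from .pipeline import feature_table


@dataclass
class SelectionConfig:
    """Cost controls for the greedy search."""

    n_iters: int = 15
    #: cheap screening ensemble used on every candidate evaluation
    screen: EnsembleConfig = field(default_factory=lambda: EnsembleConfig(
        n_rounds=2, n_estimators=10))
    #: full-budget ensemble used to extract the final importances
    final: EnsembleConfig = field(default_factory=EnsembleConfig)
    alignment_params: AlignmentParams = DEFAULT_PARAMS
    master_seed: int = 0


@dataclass
class SelectionTrace:
    selected: list[str]
    steps: pd.DataFrame      # per-step pooled metrics
    importances: pd.Series   # final forest importances over the selected set


def _guide_folds(dataset: TrainingDataset, master_seed: int):
    """(train_pos, train_neg, test_records) per held-out guide."""
    folds = []
    for gid in dataset.guides():
        train_pos = dataset.positives[dataset.positives["guide_id"] != gid]
        train_neg = dataset.negatives[dataset.negatives["guide_id"] != gid]
        test_pos = dataset.positives[dataset.positives["guide_id"] == gid]
        pool = dataset.negatives[dataset.negatives["guide_id"] == gid]
        fseed = _fold_seed(master_seed, f"select:{gid}")
        test_neg = pool.sample(n=min(len(test_pos), len(pool)), random_state=fseed)
        folds.append((train_pos, train_neg, pd.concat([test_pos, test_neg])))
    return folds


def forward_select(
    dataset: TrainingDataset,
    genome: Mapping[str, str],
    config: SelectionConfig | None = None,
    candidate_features: Sequence[str] | None = None,
    features: pd.DataFrame | None = None,
) -> SelectionTrace:
    """Greedy forward selection under leave-one-guide-out r^2.

    ``features`` may be precomputed (rows for every dataset record);
    otherwise it is built once at ``config.alignment_params``.  Candidates
    default to all numeric feature columns that are not entirely missing.
    """
    config = config or SelectionConfig()
    all_records = pd.concat([dataset.positives, dataset.negatives])
    if features is None:
        features = feature_table(all_records, genome, config.alignment_params)
    targets = all_records["target_value"].astype(float)
    numeric = features.select_dtypes(include=[np.number])
    if candidate_features is None:
        candidate_features = [c for c in numeric.columns
                              if not numeric[c].isna().all()
                              and not c.endswith(MISSING_SUFFIX)]
    candidates = list(candidate_features)
    if len(candidates) < 2:
        raise ValueError("need at least two candidate features")
    n_iters = config.n_iters
    if n_iters > len(candidates):
        warnings.warn(f"n_iters {n_iters} > {len(candidates)} candidates; truncating")
        n_iters = len(candidates)

    folds = _guide_folds(dataset, config.master_seed)
    # balanced rounds are drawn once per fold and shared across candidates
    fold_rounds = []
    for train_pos, train_neg, _ in folds:
        fd = TrainingDataset(positives=train_pos, negatives=train_neg)
        seeds = round_seeds(config.master_seed, config.screen.n_rounds)
        fold_rounds.append([sample_round(fd, s) for s in seeds])

    def _evaluate(cols: list[str]) -> tuple[float, dict]:
        obs_all, pred_all, lab_all = [], [], []
        for (train_pos, train_neg, test_records), sampled in zip(folds, fold_rounds):
            train_idx = train_pos.index.union(train_neg.index)
            model = train(sampled, features.loc[train_idx, cols],
                          targets.loc[train_idx], config=config.screen)
            scores = predict(model, features.loc[test_records.index, cols])["score"]
            obs_all.append(test_records["target_value"].astype(float))
            pred_all.append(scores)
            lab_all.append(test_records["label"])
        obs = pd.concat(obs_all)
        pred = pd.concat(pred_all)
        lab = pd.concat(lab_all)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = metric_suite(obs, pred, lab)
        r2 = m["pearson_r2"] if m["pearson_r2"] is not None else -np.inf
        return r2, m

    selected: list[str] = []
    step_rows = []
    remaining = list(candidates)
    for step in range(n_iters):
        best_c, best_r2, best_m = None, -np.inf, None
        for c in remaining:
            r2, m = _evaluate(selected + [c])
            if r2 > best_r2:
                best_c, best_r2, best_m = c, r2, m
        selected.append(best_c)
        remaining.remove(best_c)
        step_rows.append({"feature": best_c, **best_m})

    steps = pd.DataFrame(step_rows)
    importances = pd.Series(dtype=float)
    if selected:
        full = TrainingDataset(positives=dataset.positives, negatives=dataset.negatives)
        seeds = round_seeds(config.master_seed, config.final.n_rounds)
        sampled = [sample_round(full, s) for s in seeds]
        model = train(sampled, features[selected], targets, config=config.final)
        importances = ensemble_importances(model)
    return SelectionTrace(selected, steps, importances)


def ensemble_importances(model) -> pd.Series:
    """Mean member importances over the model's registry, normalized to 1."""
    imp = np.mean([m.feature_importances_ for m in model.members], axis=0)
    s = pd.Series(imp, index=model.feature_registry)
    total = s.sum()
    return s / total if total > 0 else s


def importance_correlation_matrix(
    dataset: TrainingDataset,
    features: pd.DataFrame,
    config: EnsembleConfig | None = None,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Signed pairwise feature correlations plus normalized forest importances.

    Constant features yield NaN (null-flagged) correlations.  This is the
    data behind a feature-relationship graph: node size = importance, edge
    weight = correlation.
    """
    config = config or EnsembleConfig()
    numeric = features.select_dtypes(include=[np.number])
    corr = numeric.corr()  # pairwise Pearson; constant columns become NaN
    targets = pd.concat([dataset.positives, dataset.negatives])["target_value"].astype(float)
    seeds = round_seeds(master_seed, config.n_rounds)
    sampled = [sample_round(dataset, s) for s in seeds]
    model = train(sampled, numeric, targets, config=config)
    return corr, ensemble_importances(model)


# ---------------------------------------------------------------------------
# mechanism-probing statistics


def wobble_contingency(alignments: Sequence[GuideTargetAlignment]) -> pd.DataFrame:
    """Wobble vs non-wobble mismatch counts binned by mismatches per site."""
    rows: dict[int, list[int]] = {}
    for aln in alignments:
        if aln.n_mismatch == 0:
            continue
        wob = sum(classify_mismatch(g, t) == WOBBLE for g, t in aln.mismatch_pairs)
        bin_counts = rows.setdefault(aln.n_mismatch, [0, 0])
        bin_counts[0] += wob
        bin_counts[1] += aln.n_mismatch - wob
    table = pd.DataFrame(rows, index=["wobble", "non_wobble"]).T.sort_index()
    return table


def wobble_enrichment_test(
    alignments: Sequence[GuideTargetAlignment],
) -> tuple[float, float, pd.DataFrame]:
    """Chi-square test of wobble-fraction independence across mismatch bins.

    Bins whose expected counts fall below 1 are merged into their lower
    neighbor (with a warning).  Returns (statistic, p, contingency table).
    """
    table = wobble_contingency(alignments)
    table = table[table.sum(axis=1) > 0]
    if len(table) < 2:
        raise ValueError("need >= 2 mismatch-count bins with mismatches")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: one mismatch class never observed")
    while len(table) >= 2:
        _, _, _, expected = stats.chi2_contingency(table.values)
        if (expected >= 1).all():
            break
        warnings.warn("merging sparse mismatch bins (expected count < 1)")
        # fold the thinnest bin into its adjacent neighbor
        pos = int(np.argmin(table.sum(axis=1).values))
        nbr = pos - 1 if pos > 0 else pos + 1
        vals = table.values.copy()
        vals[nbr] += vals[pos]
        table = pd.DataFrame(np.delete(vals, pos, axis=0), columns=table.columns,
                             index=table.index.delete(pos))
    if len(table) < 2:
        raise ValueError("bin merging left fewer than 2 bins")
    chi2, p, _, _ = stats.chi2_contingency(table.values)
    return float(chi2), float(p), table


def enthalpy_tail_permutation_test(
    enthalpies,
    frequencies,
    n_perm: int = 1000,
    tail_percentiles: tuple[float, float] = (5.0, 95.0),
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation test for depressed cleavage at enthalpy extremes.

    The enthalpy values are fixed while cleavage frequencies are shuffled;
    each iteration records the mean frequency over the union of the two
    extreme-enthalpy tails.  The p-value is the (add-one smoothed)
    proportion of shuffles whose tail mean falls below the observed one.
    Returns (observed tail mean, p).
    """
    enth = np.asarray(enthalpies, dtype=float)
    freq = np.asarray(frequencies, dtype=float)
    if len(enth) != len(freq):
        raise ValueError("enthalpy and frequency vectors differ in length")
    if len(enth) < 20:
        raise ValueError("need >= 20 records for the tail permutation test")
    if np.allclose(freq, freq[0]):
        warnings.warn("all cleavage frequencies equal; permutation p = 1 by convention")
        return float(freq[0]), 1.0
    lo, hi = np.percentile(enth, tail_percentiles)
    in_tail = (enth < lo) | (enth > hi)
    if not in_tail.any():
        raise ValueError("empty enthalpy tails; widen tail_percentiles")
    observed = float(freq[in_tail].mean())
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        perm = rng.permutation(freq)
        if perm[in_tail].mean() < observed:
            k += 1
    p = (k + 1) / (n_perm + 1)
    return observed, float(p)
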