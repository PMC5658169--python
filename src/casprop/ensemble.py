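"""Ensemble of random-forest regressors over balanced training rounds.

One forest is fitted per balanced resample (round); the cleavage-propensity
score of a site is the mean of the member predictions, which inherits the
[0, 1] range of the regression target.  A classification variant (forests
of probability estimators on the binary cleaved/uncleaved label) is
available and produces very similar rankings; regression is the default
because it preserves the graded cleavage intensities.

Null-flagged features (NaN) are imputed with the training median and
accompanied by a 0/1 missingness-indicator column, so a forest can still
split on "was this measured at all".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .align import AlignmentParams
from .dataset import SampledDataset

MISSING_SUFFIX = "__missing"


@dataclass
class EnsembleConfig:
    """Hyperparameters; the forest settings are recorded in model metadata."""

    n_rounds: int = 100
    n_estimators: int = 10
    max_depth: int | None = None
    max_features: float | str | None = 1.0
    min_samples_leaf: int = 1
    mode: str = "regression"  # or "classification"
    master_seed: int = 0

    def forest(self, seed: int):
        kwargs = dict(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )
        if self.mode == "classification":
            return RandomForestClassifier(**kwargs)
        return RandomForestRegressor(**kwargs)


@dataclass
class TrainedEnsemble:
    members: list
    feature_registry: list[str]          # post-imputation column order
    raw_feature_names: list[str]         # pre-imputation column order
    impute_medians: pd.Series
    alignment_params: AlignmentParams
    config: EnsembleConfig
    metadata: dict = field(default_factory=dict)

    def save(self, path):
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedEnsemble":
        return joblib.load(path)


@dataclass
class PropensityScore:
    """Ensemble-mean score with the spread of member predictions."""

    value: float
    member_min: float
    member_max: float
    member_sd: float


def _prepare_matrix(
    X: pd.DataFrame, medians: pd.Series, registry: Sequence[str]
) -> pd.DataFrame:
    """Median-impute and attach missingness indicators, in registry order."""
    out = {}
    for col in medians.index:
        series = X[col]
        out[col] = series.fillna(medians[col])
        ind = f"{col}{MISSING_SUFFIX}"
        if ind in registry:
            out[ind] = series.isna().astype(float)
    return pd.DataFrame(out)[list(registry)]


def train(
    sampled: Sequence[SampledDataset],
    features: pd.DataFrame,
    targets: pd.Series,
    config: EnsembleConfig | None = None,
    alignment_params: AlignmentParams | None = None,
) -> TrainedEnsemble:
    """Fit one forest per balanced round.

    ``features`` rows are indexed by record id; each round's records index
    into it.  Regression mode fits the harmonized target in [0, 1];
    classification mode fits the binary cleaved label (target > 0).
    """
    config = config or EnsembleConfig()
    alignment_params = alignment_params or AlignmentParams()
    if len(sampled) == 0:
        raise ValueError("no sampled rounds supplied")
    numeric = features.select_dtypes(include=[np.number])
    medians = numeric.median()
    medians = medians.fillna(0.0)  # all-missing column: impute 0, keep the indicator
    registry: list[str] = []
    for col in numeric.columns:
        registry.append(col)
        if numeric[col].isna().any():
            registry.append(f"{col}{MISSING_SUFFIX}")
    X_all = _prepare_matrix(numeric, medians, registry)

    rng = np.random.default_rng(config.master_seed)
    members = []
    for rnd in sampled:
        idx = rnd.records.index
        y = targets.loc[idx]
        if config.mode == "classification":
            y = (y > 0).astype(int)
            if y.nunique() < 2:
                raise ValueError(f"round {rnd.round_seed}: constant labels")
        elif y.nunique() < 2:
            raise ValueError(f"round {rnd.round_seed}: constant target values")
        forest = config.forest(rng.integers(2**31))
        forest.fit(X_all.loc[idx].values, y.values)
        members.append(forest)
    return TrainedEnsemble(
        members=members,
        feature_registry=registry,
        raw_feature_names=list(numeric.columns),
        impute_medians=medians,
        alignment_params=alignment_params,
        config=config,
        metadata={
            "n_rounds": len(members),
            "mode": config.mode,
            "n_estimators": config.n_estimators,
            "max_depth": config.max_depth,
            "max_features": config.max_features,
        },
    )


def member_predictions(model: TrainedEnsemble, features: pd.DataFrame) -> np.ndarray:
    """(n_members, n_records) raw member outputs."""
    missing = [c for c in model.raw_feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature registry mismatch; missing: {missing}")
    X = _prepare_matrix(features, model.impute_medians, model.feature_registry).values
    preds = []
    for forest in model.members:
        if model.config.mode == "classification":
            proba = forest.predict_proba(X)
            cls1 = list(forest.classes_).index(1) if 1 in forest.classes_ else None
            preds.append(proba[:, cls1] if cls1 is not None else np.zeros(len(X)))
        else:
            preds.append(forest.predict(X))
    return np.vstack(preds)


def predict(model: TrainedEnsemble, features: pd.DataFrame) -> pd.DataFrame:
    """Ensemble-mean propensity per record, with member spread columns."""
    P = member_predictions(model, features)
    return pd.DataFrame(
        {
            "score": P.mean(axis=0),
            "member_min": P.min(axis=0),
            "member_max": P.max(axis=0),
            "member_sd": P.std(axis=0, ddof=0),
        },
        index=features.index,
    )


def predict_one(model: TrainedEnsemble, fv: dict[str, float]) -> PropensityScore:
    df = predict(model, pd.DataFrame([fv]))
    row = df.iloc[0]
    return PropensityScore(row["score"], row["member_min"], row["member_max"], row["member_sd"])


def score_thresholds(
    model: TrainedEnsemble,
    cleaved_features: pd.DataFrame,
    quantiles: Sequence[float] = (0.95, 0.50),
) -> dict[float, float]:
    """Score cutoffs exceeded by the given fraction of cleaved sites.

    ``quantiles=(0.95, 0.5)`` returns the strict and lenient thresholds: the
    scores that 95% and 50% of predicted cleaved sites surpass.
    """
    if len(cleaved_features) < 20:
        raise ValueError("need >= 20 cleaved records to set thresholds")
    scores = predict(model, cleaved_features)["score"].values
    return {float(q): float(np.quantile(scores, 1.0 - q)) for q in quantiles}
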