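"""Harmonize heterogeneous per-study read counts onto a common scale.

Genome-wide cleavage assays (GUIDE-seq, HTGTS, BLESS) report read counts on
incomparable scales.  Counts are log-transformed (the transformed counts are
approximately normal), then each study is linearly calibrated onto the
reference study's scale by ordinary least squares over targets shared
between the two (same guide, overlapping genomic interval).  The regression
target is the calibrated log count divided by the dataset maximum, so it
lives in [0, 1]; uncleaved sites sit at exactly 0.

Record tables are pandas DataFrames with (at least) the columns
``study, guide_id, chrom, start, end, strand, raw_reads, label`` where
``label`` is "cleaved" or "uncleaved" (see :mod:`casprop.io`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: coordinate slack (nt) when matching shared targets across studies; PAM
#: relocation can shift a site's window by up to 2 nt
SHARED_SLACK = 2


@dataclass(frozen=True)
class StudyCalibration:
    """Linear map from one study's log counts onto the reference scale."""

    study: str
    slope: float
    intercept: float
    n_shared: int
    fit_r2: float

    def apply(self, log_values):
        return self.slope * np.asarray(log_values, dtype=float) + self.intercept


def log_transform(raw_reads, base: float = 10.0, pseudocount: float = 1.0):
    """log(raw + pseudocount); strictly increasing, 0 reads -> 0 by default."""
    arr = np.asarray(raw_reads, dtype=float)
    if np.any(arr < 0):
        raise ValueError("read counts must be non-negative")
    return np.log(arr + pseudocount) / math.log(base)


def inverse_log_transform(values, base: float = 10.0, pseudocount: float = 1.0):
    return np.power(base, np.asarray(values, dtype=float)) - pseudocount


def _match_shared(study_df: pd.DataFrame, reference_df: pd.DataFrame) -> pd.DataFrame:
    """Pair study/reference records of the same guide whose windows overlap.

    Intervals are given +/-SHARED_SLACK nt of slack to absorb PAM
    relocation.  Returns a frame with columns ``study_log`` and ``ref_log``.
    """
    merged = study_df.merge(
        reference_df,
        on=["guide_id", "chrom", "strand"],
        suffixes=("_study", "_ref"),
    )
    overlap = (merged["start_study"] < merged["end_ref"] + SHARED_SLACK) & (
        merged["end_study"] > merged["start_ref"] - SHARED_SLACK
    )
    merged = merged[overlap]
    return pd.DataFrame(
        {"study_log": merged["log_reads_study"].values, "ref_log": merged["log_reads_ref"].values}
    )


def fit_calibration(
    study_df: pd.DataFrame, reference_df: pd.DataFrame, study: str | None = None
) -> StudyCalibration:
    """OLS fit of reference log counts on study log counts over shared targets.

    Both frames must already carry ``log_reads``.  Requires at least two
    shared targets and non-constant study values.
    """
    name = study if study is not None else str(study_df["study"].iloc[0])
    shared = _match_shared(study_df, reference_df)
    if len(shared) < 2:
        raise ValueError(
            f"study {name!r}: {len(shared)} shared target(s) with the reference, need >= 2"
        )
    x, y = shared["study_log"].values, shared["ref_log"].values
    if np.allclose(x, x[0]):
        raise ValueError(f"study {name!r}: zero variance in shared study values")
    if np.allclose(y, y[0]):
        # degenerate but well-defined: flat reference -> slope 0
        slope, intercept, r2 = 0.0, float(y[0]), 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    return StudyCalibration(name, slope, intercept, len(shared), r2)


def harmonize_studies(
    records: pd.DataFrame,
    reference_study: str,
    base: float = 10.0,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, dict[str, StudyCalibration]]:
    """Log-transform and calibrate every study onto the reference scale.

    Only cleaved records enter the calibration fits; uncleaved records get
    ``harmonized = 0``.  Returns the augmented table and the per-study fits
    (the reference maps to itself with slope 1, intercept 0).
    """
    df = records.copy()
    df["log_reads"] = log_transform(df["raw_reads"].fillna(0), base, pseudocount)
    cleaved = df[df["label"] == "cleaved"]
    if reference_study not in set(cleaved["study"]):
        raise ValueError(f"reference study {reference_study!r} absent from cleaved records")
    ref = cleaved[cleaved["study"] == reference_study]
    calibrations: dict[str, StudyCalibration] = {
        reference_study: StudyCalibration(reference_study, 1.0, 0.0, len(ref), 1.0)
    }
    df["harmonized"] = 0.0
    for study, sub in cleaved.groupby("study", sort=True):
        if study == reference_study:
            df.loc[sub.index, "harmonized"] = sub["log_reads"]
            continue
        cal = fit_calibration(sub, ref, study=str(study))
        calibrations[str(study)] = cal
        df.loc[sub.index, "harmonized"] = cal.apply(sub["log_reads"])
    return df, calibrations


def finalize_targets(records: pd.DataFrame) -> pd.DataFrame:
    """Scale harmonized values by the dataset maximum into [0, 1].

    Calibration can push a weak site below zero; those are clamped to 0.
    Uncleaved records stay at exactly 0.
    """
    df = records.copy()
    cleaved = df["label"] == "cleaved"
    if not cleaved.any():
        raise ValueError("no cleaved records: the positive set is empty")
    peak = df.loc[cleaved, "harmonized"].max()
    if peak <= 0:
        raise ValueError("maximal harmonized value is <= 0; cannot scale")
    df["target_value"] = 0.0
    df.loc[cleaved, "target_value"] = (df.loc[cleaved, "harmonized"] / peak).clip(lower=0.0)
    return df
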