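"""End-to-end assembly: simulated or tabular records -> training dataset -> features.

This is the glue the cross-validation, feature-selection, and CLI layers
share: deduplicate and harmonize the cleaved records, mine the uncleaved
class from the genome, and turn every record into the named feature vector
under a given set of alignment parameters.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import (
    AlignmentParams,
    DEFAULT_PARAMS,
    GuideRNA,
    TargetSite,
    align_best_window_many,
    extract_flanks,
)
from .dataset import (
    MIN_NEGATIVE_SCORE,
    TrainingDataset,
    deduplicate,
    mine_negatives,
)
from .features import AnnotationTable, ShapeTables, compute_features, features_to_frame
from .harmonize import finalize_targets, harmonize_studies

RECORD_SITE_COLUMNS = ["guide_id", "guide_seq", "chrom", "start", "end", "strand",
                       "site_seq", "pam", "label"]


def sites_from_records(records: pd.DataFrame, genome: Mapping[str, str],
                       flank: int = 100) -> list[TargetSite]:
    """Materialize TargetSites (with genome flanks) for each record row."""
    sites = []
    for row in records.itertuples():
        up, down = extract_flanks(genome, row.chrom, int(row.start), int(row.end),
                                  row.strand, flank=flank)
        sites.append(TargetSite(row.chrom, int(row.start), int(row.end), row.strand,
                                row.site_seq, row.pam,
                                upstream_flank=up, downstream_flank=down))
    return sites


def assemble_training_data(
    cleaved_records: pd.DataFrame,
    genome: Mapping[str, str],
    reference_study: str,
    exclude_studies: Sequence[str] = (),
    params: AlignmentParams = DEFAULT_PARAMS,
    min_score: float = MIN_NEGATIVE_SCORE,
) -> TrainingDataset:
    """Deduplicate, harmonize, scale, and mine negatives for a cleaved table.

    ``cleaved_records`` must carry the record-schema columns plus ``study``
    and ``raw_reads``.  Negatives are mined per guide from the genome,
    excluding every known cleaved interval of that guide (including records
    later dropped by deduplication).
    """
    cleaved = cleaved_records[cleaved_records["label"] == "cleaved"].copy()
    dedup = deduplicate(cleaved, reference_study=reference_study,
                        exclude_studies=exclude_studies)
    harmonized, _ = harmonize_studies(dedup, reference_study=reference_study)
    positives = finalize_targets(harmonized).reset_index(drop=True)

    neg_parts = []
    for gid, sub in positives.groupby("guide_id", sort=True):
        guide = GuideRNA(gid, sub["guide_seq"].iloc[0])
        known = cleaved[cleaved["guide_id"] == gid]
        excl = list(zip(known["chrom"], known["start"], known["end"]))
        mined = mine_negatives(guide, genome, params=params, min_score=min_score,
                               exclude_intervals=excl)
        neg_parts.append(pd.DataFrame({
            "guide_id": gid,
            "guide_seq": guide.spacer,
            "chrom": [s.seq_id for s in mined],
            "start": [s.start for s in mined],
            "end": [s.end for s in mined],
            "strand": [s.strand for s in mined],
            "site_seq": [s.site_seq for s in mined],
            "pam": [s.pam for s in mined],
            "study": "mined",
            "raw_reads": 0,
            "label": "uncleaved",
            "target_value": 0.0,
        }))
    negatives = pd.concat(neg_parts, ignore_index=True) if neg_parts else pd.DataFrame()
    negatives.index = negatives.index + len(positives)  # disjoint record ids
    return TrainingDataset(positives=positives, negatives=negatives)


def assemble_from_simulation(sim, params: AlignmentParams = DEFAULT_PARAMS,
                             min_score: float = MIN_NEGATIVE_SCORE) -> TrainingDataset:
    """Run the assembly pipeline on a :class:`~casprop.simulate.SimulatedData`."""
    reference = sim.config.studies[0].name
    return assemble_training_data(
        sim.records, sim.genome, reference_study=reference,
        params=params, min_score=min_score,
    )


def feature_table(
    records: pd.DataFrame,
    genome: Mapping[str, str],
    params: AlignmentParams = DEFAULT_PARAMS,
    annotations: AnnotationTable | None = None,
    shape_tables: ShapeTables | None = None,
    extra_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Feature matrix (rows aligned to ``records.index``) under ``params``.

    Alignment-derived features are recomputed from scratch, so the same
    records can be re-featurized per cross-validation fold after parameter
    re-optimization.  ``extra_columns`` of the record table (e.g. external
    scores) pass through into the matrix.
    """
    frames = []
    for gid, sub in records.groupby("guide_id", sort=True):
        guide = GuideRNA(gid, sub["guide_seq"].iloc[0])
        sites = sites_from_records(sub, genome)
        alns = align_best_window_many(guide, sites, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vecs = []
            for row_idx, site, aln in zip(sub.index, sites, alns):
                extra = {c: records.at[row_idx, c] for c in extra_columns}
                vecs.append(compute_features(guide, site, aln,
                                             annotations=annotations,
                                             shape_tables=shape_tables,
                                             extra=extra))
        frame = features_to_frame(vecs)
        frame.index = sub.index
        frames.append(frame)
    out = pd.concat(frames).loc[records.index]
    return out


def combined_records(dataset: TrainingDataset) -> pd.DataFrame:
    """Positives and negatives stacked with their disjoint indices."""
    return pd.concat([dataset.positives, dataset.negatives])
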