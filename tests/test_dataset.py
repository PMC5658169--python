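"""Negative mining, study deduplication, and balanced round sampling."""

import numpy as np
import pandas as pd
import pytest

from casprop._seq import reverse_complement
from casprop.align import AlignmentParams, GuideRNA
from casprop.dataset import (
    TrainingDataset,
    deduplicate,
    mine_negatives,
    round_seeds,
    sample_round,
)
from conftest import random_seq
from oracles import enumerate_best_score


def _naive_mine(guide, genome, min_score=14.75, max_gaps=3):
    """Brute-force re-scan with the enumeration oracle as scorer."""
    hits = set()
    for seq_id, seq in genome.items():
        n = len(seq)
        for i in range(n - 2):
            # forward PAM at [i, i+3)
            if seq[i + 1 : i + 3] in ("GG", "AG") and i >= 23 and i + 3 <= n:
                best = max(
                    enumerate_best_score(guide.spacer, seq[i - w : i], 1, 0, -1.25, max_gaps)
                    for w in range(17, 24)
                )
                if best > min_score:
                    hits.add((seq_id, i - 20, i, "+"))
            # reverse PAM: forward CCN / CTN at [i, i+3)
            if seq[i : i + 2] in ("CC", "CT") and i + 26 <= n:
                start = i + 3
                best = max(
                    enumerate_best_score(
                        guide.spacer,
                        reverse_complement(seq[start : start + w]),
                        1, 0, -1.25, max_gaps,
                    )
                    for w in range(17, 24)
                )
                if best > min_score:
                    hits.add((seq_id, start, start + 20, "-"))
    return hits


class TestMineNegatives:
    def test_planted_perfect_site_found(self, rng):
        g = GuideRNA("g1", random_seq(rng, 20))
        genome = {"c": random_seq(rng, 200) + g.spacer + "TGG" + random_seq(rng, 200)}
        sites = mine_negatives(g, genome)
        hit = [s for s in sites if s.site_seq == g.spacer]
        assert len(hit) == 1
        assert hit[0].start == 200 and hit[0].pam == "TGG"

    def test_no_pam_no_sites(self):
        g = GuideRNA("g1", "ACGT" * 5)
        # alternating AT only: no GG/AG/CC/CT dinucleotides anywhere
        genome = {"c": "AT" * 300}
        assert mine_negatives(g, genome) == []

    def test_matches_bruteforce_rescan(self, rng):
        g = GuideRNA("g1", random_seq(rng, 20))
        core = random_seq(rng, 2000)
        # plant near-matches so something clears the threshold
        mut = list(g.spacer)
        mut[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[3]]
        genome = {"c": core[:900] + "".join(mut) + "AGG" + core[900:1800]}
        got = {(s.seq_id, s.start, s.end, s.strand) for s in mine_negatives(g, genome)}
        want = _naive_mine(g, genome)
        assert got == want
        assert got  # the planted 1-mismatch site is present

    def test_excludes_cleaved_overlap(self, rng):
        g = GuideRNA("g1", random_seq(rng, 20))
        genome = {"c": random_seq(rng, 100) + g.spacer + "TGG" + random_seq(rng, 100)}
        sites = mine_negatives(g, genome, exclude_intervals=[("c", 100, 120)])
        assert not any(s.start < 120 and s.end > 100 for s in sites)

    def test_reverse_complement_invariance(self, rng):
        g = GuideRNA("g1", random_seq(rng, 20))
        mut = list(g.spacer)
        mut[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[7]]
        fwd = random_seq(rng, 400) + "".join(mut) + "TGG" + random_seq(rng, 400)
        n = len(fwd)
        a = mine_negatives(g, {"c": fwd})
        b = mine_negatives(g, {"c": reverse_complement(fwd)})
        mirror = {(n - s.end, n - s.start, "-" if s.strand == "+" else "+") for s in a}
        got = {(s.start, s.end, s.strand) for s in b}
        assert got == mirror and len(a) > 0


class TestDeduplicate:
    def _df(self):
        return pd.DataFrame({
            "study": ["Tsai", "Tsai", "Kleinstiver", "Frock", "Ran"],
            "guide_id": ["g1", "g1", "g1", "g2", "g3"],
            "chrom": "c", "start": [0, 50, 0, 0, 0], "end": [20, 70, 20, 20, 20],
            "strand": "+", "raw_reads": [10, 5, 8, 3, 2], "label": "cleaved",
        })

    def test_reference_collection_kept(self):
        out = deduplicate(self._df())
        g1 = out[out["guide_id"] == "g1"]
        assert set(g1["study"]) == {"Tsai"} and len(g1) == 2

    def test_excluded_study_dropped(self):
        out = deduplicate(self._df())
        assert "Frock" not in set(out["study"])

    def test_single_study_guide_unchanged(self):
        out = deduplicate(self._df())
        assert len(out[out["guide_id"] == "g3"]) == 1

    def test_missing_reference_falls_back_with_warning(self):
        df = self._df()
        df.loc[df["guide_id"] == "g1", "study"] = ["Kleinstiver", "Kleinstiver", "Ran"]
        with pytest.warns(UserWarning, match="reference study"):
            out = deduplicate(df)
        g1 = out[out["guide_id"] == "g1"]
        assert set(g1["study"]) == {"Kleinstiver"}  # most targets wins


def _toy_dataset(rng, n_pos=10, n_neg=40, guides=("g1", "g2")):
    parts_p, parts_n = [], []
    rid = 0
    for g in guides:
        for lab, n, bucket in (("cleaved", n_pos, parts_p), ("uncleaved", n_neg, parts_n)):
            df = pd.DataFrame({
                "guide_id": g,
                "chrom": "c",
                "start": np.arange(n) * 100 + rid,
                "end": np.arange(n) * 100 + 20 + rid,
                "strand": "+",
                "label": lab,
                "target_value": rng.uniform(0.1, 1, n) if lab == "cleaved" else 0.0,
            })
            df.index = range(rid, rid + n)
            rid += n
            bucket.append(df)
    return TrainingDataset(pd.concat(parts_p), pd.concat(parts_n))


class TestSampleRound:
    def test_exact_balance_2x(self, rng):
        ds = _toy_dataset(rng)
        s = sample_round(ds, seed=5)
        for g in ("g1", "g2"):
            sub = s.records[s.records["guide_id"] == g]
            assert (sub["label"] == "cleaved").sum() == 20
            assert (sub["label"] == "uncleaved").sum() == 20

    def test_seed_reproducibility(self, rng):
        ds = _toy_dataset(rng)
        a = sample_round(ds, seed=11).records
        b = sample_round(ds, seed=11).records
        pd.testing.assert_frame_equal(a, b)
        c = sample_round(ds, seed=12).records
        assert not a.index.equals(c.index)

    def test_insufficient_negatives_names_guide(self, rng):
        ds = _toy_dataset(rng, n_pos=10, n_neg=5)
        with pytest.raises(ValueError, match="g1"):
            sample_round(ds, seed=0)

    def test_bootstrap_inclusion_frequency(self, rng):
        """Each positive appears in a round with prob ~ 1 - (1-1/n)^(2n)."""
        ds = _toy_dataset(rng, n_pos=10, n_neg=40, guides=("g1",))
        n = 10
        expect = 1 - (1 - 1 / n) ** (2 * n)
        rounds = 1000
        seen = np.zeros(n)
        ids = list(ds.positives.index)
        for s in round_seeds(123, rounds):
            drawn = set(sample_round(ds, s).records.index)
            for k, rid in enumerate(ids):
                if rid in drawn:
                    seen[k] += 1
        freq = seen / rounds
        se = np.sqrt(expect * (1 - expect) / rounds)
        assert np.all(np.abs(freq - expect) < 3 * se + 1e-9)

    def test_duplicate_positives_rejected(self, rng):
        ds = _toy_dataset(rng)
        dup = pd.concat([ds.positives, ds.positives.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            TrainingDataset(dup, ds.negatives)
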