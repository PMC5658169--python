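"""Mismatch chemistry, enthalpy additivity, and feature-vector invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casprop._seq import reverse_complement
from casprop.align import AlignmentParams, GuideRNA, TargetSite, align_best_window
from casprop.features import (
    MISMATCH_CLASSES,
    AnnotationTable,
    ShapeTables,
    classify_mismatch,
    compute_features,
    feature_names,
    features_to_frame,
)
from casprop.thermo import NN_DELTA_H, nn_enthalpy
from conftest import random_seq

P = AlignmentParams()


class TestMismatchClass:
    @pytest.mark.parametrize(
        "guide,target_strand,expected",
        [
            ("G", "T", "wobble"),       # rG.dT
            ("T", "G", "wobble"),       # rU.dG
            ("A", "G", "transition_RR"),
            ("G", "A", "transition_RR"),
            ("C", "T", "transition_YY"),
            ("T", "C", "transition_YY"),
            ("A", "C", "transversion"),
            ("A", "A", "transition_RR"),  # both purines
            ("C", "C", "transition_YY"),  # both pyrimidines
        ],
    )
    def test_classes(self, guide, target_strand, expected):
        assert classify_mismatch(guide, target_strand) == expected

    def test_matched_pair_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            classify_mismatch("A", "T")
        with pytest.raises(ValueError, match="matched"):
            classify_mismatch("G", "C")

    def test_every_mismatch_maps_to_exactly_one_class(self):
        from casprop._seq import complement

        for g in "ACGT":
            for t in "ACGT":
                if t == complement(g):
                    continue
                assert classify_mismatch(g, t) in MISMATCH_CLASSES


class TestEnthalpy:
    def test_single_base_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert nn_enthalpy("A") == 0.0

    def test_hand_summed_acgt(self):
        want = NN_DELTA_H["AC"] + NN_DELTA_H["CG"] + NN_DELTA_H["GT"]
        assert nn_enthalpy("ACGT") == pytest.approx(want)
        assert nn_enthalpy("ACGT") == pytest.approx(-8.4 - 10.6 - 8.4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=40))
    def test_reverse_complement_symmetry(self, seq):
        assert nn_enthalpy(seq) == pytest.approx(nn_enthalpy(reverse_complement(seq)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=20),
           st.text(alphabet="ACGT", min_size=2, max_size=20))
    def test_additivity_at_junction(self, x, y):
        junction = NN_DELTA_H[x[-1] + y[0]]
        assert nn_enthalpy(x + y) == pytest.approx(nn_enthalpy(x) + nn_enthalpy(y) + junction)

    def test_ambiguous_base_skips_stack(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            assert nn_enthalpy("ANT") == 0.0


def _make_site(window, upstream, downstream, pam="TGG", strand="+", seq_id="chr1", start=1000):
    return TargetSite(seq_id, start, start + len(window), strand, window, pam,
                      upstream_flank=upstream, downstream_flank=downstream)


class TestFeatureVector:
    def _perfect(self, rng):
        spacer = random_seq(rng, 20)
        g = GuideRNA("g1", spacer)
        site = _make_site(spacer, random_seq(rng, 100), random_seq(rng, 100))
        aln = align_best_window(g, site, P)
        return g, site, aln

    def test_perfect_match_vector(self, rng):
        g, site, aln = self._perfect(rng)
        fv = compute_features(g, site, aln)
        assert fv["n_mismatch"] == 0
        assert all(fv[f"n_{c}"] == 0 for c in MISMATCH_CLASSES)
        assert fv["pam_NGG"] == 1.0
        assert fv["alignment_score"] == 20.0

    def test_gc_extremes(self, rng):
        g = GuideRNA("g1", "GGGGCCCCGGGGCCCCGGGG")
        site = _make_site("GGGGCCCCGGGGCCCCGGGG", random_seq(rng, 50), random_seq(rng, 50))
        fv = compute_features(g, site, align_best_window(g, site, P))
        assert fv["gc_site"] == 1.0

    def test_class_counts_sum_to_n_mismatch(self, rng):
        for _ in range(20):
            g = GuideRNA("g1", random_seq(rng, 20))
            w = list(g.spacer)
            k = int(rng.integers(1, 6))
            for i in rng.choice(20, size=k, replace=False):
                w[i] = rng.choice([b for b in "ACGT" if b != w[i]])
            site = _make_site("".join(w), random_seq(rng, 30), random_seq(rng, 30))
            aln = align_best_window(g, site, P)
            fv = compute_features(g, site, aln)
            assert sum(fv[f"n_{c}"] for c in MISMATCH_CLASSES) == fv["n_mismatch"]

    def test_one_hot_sums(self, rng):
        g, site, aln = self._perfect(rng)
        fv = compute_features(g, site, aln)
        assert fv["pam_NGG"] + fv["pam_NAG"] + fv["pam_other"] == 1.0
        for pos in (2, 4, 5, 20):
            assert sum(fv[f"pos{pos}_{nt}"] for nt in "ACGT") == 1.0
        for k in range(1, 6):
            assert sum(fv[f"pamdown{k}_{nt}"] for nt in "ACGT") == 1.0

    def test_purity(self, rng):
        g, site, aln = self._perfect(rng)
        a = features_to_frame([compute_features(g, site, aln)])
        b = features_to_frame([compute_features(g, site, aln)])
        pd.testing.assert_frame_equal(a, b)

    def test_missing_plugins_are_nan_not_zero(self, rng):
        g, site, aln = self._perfect(rng)
        fv = compute_features(g, site, aln)
        for name in ("mgw_pam", "bending_stiffness", "dnase_hs", "cpg_island",
                     "expression", "sgrna_folding_energy"):
            assert math.isnan(fv[name])

    def test_annotations_and_shape_lookups(self, rng):
        g, site, aln = self._perfect(rng)
        ann = AnnotationTable(pd.DataFrame({
            "seq_id": ["chr1", "chr1"],
            "start": [900, 990],
            "end": [1100, 1010],
            "dnase_hs": [1, 0],
            "exon_strand": ["-", None],
            "cpg": [0, 1],
            "expression": [5.5, np.nan],
        }))
        import itertools
        mgw = {"".join(p): 5.0 for p in itertools.product("ACGT", repeat=5)}
        stiff = {"".join(p): 2.0 for p in itertools.product("ACGT", repeat=2)}
        fv = compute_features(g, site, aln, annotations=ann,
                              shape_tables=ShapeTables(mgw=mgw, stiffness=stiff),
                              folding_provider=lambda gd: -3.25)
        assert fv["dnase_hs"] == 1.0
        assert fv["exon_coding"] == 0.0 and fv["exon_opposite"] == 1.0
        assert fv["cpg_island"] == 1.0
        assert fv["expression"] == 5.5
        assert fv["mgw_pam"] == 5.0
        assert fv["bending_stiffness"] == 2.0
        assert fv["sgrna_folding_energy"] == -3.25

    def test_frame_registry_order_and_extras(self, rng):
        g, site, aln = self._perfect(rng)
        fv = compute_features(g, site, aln, extra={"cfd_score": 0.7})
        df = features_to_frame([fv])
        names = feature_names()
        assert list(df.columns[: len(names)]) == names
        assert "cfd_score" in df.columns
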