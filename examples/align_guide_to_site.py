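"""Align an sgRNA spacer to a genomic site that carries a DNA bulge.

The aligner is a global dynamic program with a hard budget of three
single-column indels: an unpaired DNA base (DNA bulge) or unpaired RNA
base (RNA bulge) each cost the gap penalty, mismatches cost the mismatch
penalty, and seven window lengths (17-23 nt, anchored at the PAM) compete
for the best score.
"""

from casprop import AlignmentParams, GuideRNA, TargetSite, align_best_window

guide = GuideRNA("demo", "GACGTACGTACGTACGTACG")

# genomic site: the protospacer with an extra 'T' inserted (a DNA bulge)
# and one mismatch near the PAM, followed by an AGG PAM
site = TargetSite(
    seq_id="chr1", start=1000, end=1021, strand="+",
    site_seq="GACGTACGTATCGTACGTACC", pam="AGG",
    upstream_flank="ATATATATAT", downstream_flank="GCGCGCGCGC",
)

aln = align_best_window(guide, site, AlignmentParams())

print("guide :", aln.aligned_guide)
print("site  :", aln.aligned_target, f"(window {aln.chosen_window} nt)")
print(f"score {aln.score}: {aln.n_match} matches, {aln.n_mismatch} mismatches, "
      f"{aln.n_dna_bulge} DNA bulge(s), {aln.n_rna_bulge} RNA bulge(s)")
print("mismatch positions (1 = PAM-proximal):", aln.mismatch_positions)
# The bulge costs -1.25 but rescues the register, so the gapped alignment
# beats any gapless pairing of the same site.
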