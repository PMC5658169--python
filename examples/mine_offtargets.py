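"""Scan a genome for candidate (off-)target sites of one guide.

Every NGG/NAG-adjacent window on either strand is aligned to the spacer;
windows scoring above 14.75 (the complementarity level that ~95% of real
cleaved sites exceed) are candidate off-targets.  Here the genome is
simulated with planted near-matches, so the miner has something to find.
"""

from casprop.align import best_window_scores
from casprop.dataset import mine_negatives
from casprop.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(SimConfig(genome_length=80_000, n_guides=1,
                                 cleaved_per_guide=20, decoys_per_guide=60,
                                 master_seed=7))
guide = sim.guides[0]
cleaved = sim.truth[sim.truth["label"] == "cleaved"]
exclude = list(zip(cleaved["chrom"], cleaved["start"], cleaved["end"]))

sites = mine_negatives(guide, sim.genome, exclude_intervals=exclude)
scores = best_window_scores(guide, sites)

print(f"guide {guide.id} ({guide.spacer})")
print(f"{len(sites)} candidate sites score > 14.75 and avoid known cleaved loci")
ranked = sorted(zip(scores, sites), key=lambda t: -t[0])[:5]
for score, s in ranked:
    print(f"  {s.seq_id}:{s.start}-{s.end} ({s.strand})  PAM {s.pam}  score {score:.2f}")
# Scores close to 20 are near-perfect complements -- the sites most at risk
# of unintended cleavage.
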