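"""Train the balanced-forest ensemble and score candidate sites.

The training set combines harmonized cleaved sites (regression target =
max-normalized log read count, in [0, 1]) with genome-mined uncleaved
sites.  Each ensemble member is a random-forest regressor fitted on one
class-balanced bootstrap round; the propensity score is the member mean.
"""

from casprop.dataset import round_seeds, sample_round
from casprop.ensemble import EnsembleConfig, predict, score_thresholds, train
from casprop.pipeline import assemble_from_simulation, combined_records, feature_table
from casprop.simulate import SimConfig, simulate_dataset

sim = simulate_dataset(SimConfig(genome_length=120_000, n_guides=3,
                                 cleaved_per_guide=50, decoys_per_guide=150,
                                 master_seed=11))
dataset = assemble_from_simulation(sim)
records = combined_records(dataset)
features = feature_table(records, sim.genome)

config = EnsembleConfig(n_rounds=20, n_estimators=10, master_seed=11)
sampled = [sample_round(dataset, s) for s in round_seeds(11, config.n_rounds)]
model = train(sampled, features, records["target_value"].astype(float), config=config)

scores = predict(model, features)
cleaved = dataset.positives.index
uncleaved = dataset.negatives.index
print(f"trained {len(model.members)} members on {len(dataset.positives)} cleaved / "
      f"{len(dataset.negatives)} mined uncleaved sites")
print(f"mean propensity: cleaved {scores.loc[cleaved, 'score'].mean():.3f}, "
      f"uncleaved {scores.loc[uncleaved, 'score'].mean():.3f}")

th = score_thresholds(model, features.loc[cleaved])
print(f"thresholds: 95% of cleaved sites score above {th[0.95]:.3f} (strict), "
      f"50% above {th[0.5]:.3f} (lenient)")
# A new site scoring above the strict threshold behaves like nearly all
# experimentally cleaved sites and deserves scrutiny as an off-target.
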