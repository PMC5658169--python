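# Methods

## Model overview

`casprop` treats cleavage propensity as a regression problem: the target is
the max-normalized, cross-study-calibrated log read count of a site (0 for
uncleaved sites), and the predictor is an ensemble of random-forest
regressors over a named feature vector. The package's assumptions, in
order of importance:

1. Cleavage frequency is a monotone-ish but nonlinear function of
   sgRNA–DNA complementarity, which the forest can capture without a
   parametric form.
2. Bulges (single-nucleotide indels in the heteroduplex) are real events
   and must be representable in the alignment; at most three per pair.
3. Log read counts from different assays are related to the reference
   assay's scale approximately linearly over shared targets.
4. Uncleaved sites carry signal: sites with high complementarity that were
   *not* cleaved constrain the model, so they are mined deliberately
   rather than sampled at random from the genome.

## The gap-budgeted aligner

State `(i, j, g)`: `i` spacer bases and `j` site bases consumed with
exactly `g` gap columns used, `g ≤ 3`. Transitions are
match/mismatch (diagonal) and single-column indels (gap in either row,
incrementing `g`). No affine extension: the budget bounds the *count* of
gap columns, so adjacent gaps are legal but each costs one unit. Scores
are exact for quarter-unit penalties in float arithmetic.

Determinism is guaranteed by an explicit tie-break: maximum score, then
fewest gap columns, then fewest mismatches, then the PAM-proximal-most gap
placement with a guide-row gap preferred over a target-row gap in the same
column. The last two rules are resolved during traceback (gap moves taken
first, walking from the PAM-proximal end). Window search ties prefer the
window closest to 20 nt, then the shorter one.

Three implementations share this definition and are cross-checked in the
test suite: a single-pair Python DP with traceback (produces the
alignment strings), a batched numpy kernel (score-only, vectorized over
thousands of candidate windows, used by mining), and per-gap-layer
maximum-match profiles. The profiles exploit a closed form: with the
match reward fixed, a window of length `w` aligned with exactly `g` gaps
has a fixed number of paired columns, so the optimal score under *any*
(mismatch, gap) penalty pair follows arithmetically from the maximum match
count per layer. A dense penalty-grid search therefore costs one kernel
pass per guide, not one per grid point. All three routes are verified
against a brute-force enumeration over explicit gap placements.

## Alignment-parameter optimization

Grid: match fixed at 1.0, mismatch ∈ {0 … −1.5}, gap ∈ {−0.25 … −3.0},
step 0.25 (84 points, configurable). Objective: mean over guides of the
squared Pearson correlation between best-window scores and observed
frequencies, computed over non-exact-match targets (exact matches pin the
maximal score and are removed). Ties prefer the least-negative gap, then
the least-negative mismatch penalty — the least-punitive model consistent
with the data. Degenerate inputs (one usable target, constant scores
everywhere) raise errors naming the guide.

## PAM relocation

Sites reported with rare PAMs are often mis-registered bulge sites. For a
non-NGG site the PAM coordinates are shifted by up to 2 nt — order 0, +1,
−1, +2, −2 with downstream (3' in the site's orientation) first — looking
for an NGG; failing that the same search runs for NAG; failing that the
site is kept unchanged. The protospacer window moves with the PAM. The
downstream-first order at equal distance is a convention; the source
protocol does not pin it down, and it is recorded here so it can be
revisited.

## Feature engineering

Mismatch chemistry is evaluated in the RNA:DNA heteroduplex: the guide
base faces the *complement* of the protospacer-sense site base. Wobble is
rG·dT or rU·dG (checked first); then purine–purine and
pyrimidine–pyrimidine pairs are the two transition classes; all else is
transversion. Positions are numbered 1..20 from the PAM-proximal base; a
DNA bulge takes the position of its nearest PAM-proximal guide base.

Duplex enthalpy sums unified nearest-neighbor stacking terms (kcal/mol,
dinucleotide table embedded as versioned constants, initiation terms
omitted — only differences over a fixed 223-nt window matter, i.e. 100 nt
of flank on each side of the 23-nt site+PAM). The table is symmetric
under reverse complement, which a property test asserts.

GC content is reported separately for the 20-nt window and each 100-nt
flank. DNA-shape descriptors (minor groove width over the 6-mer around
the PAM via pentamer lookup; bending stiffness over the site via
dinucleotide lookup) and chromatin annotations (DNase hypersensitivity,
exon strand, CpG island, expression, by interval overlap) are pluggable:
absent inputs yield NaN, never silent zeros. sgRNA folding energy is a
provider interface for an external folding tool; the default is null
because these features contribute little when all samples of a guide
share them.

## Harmonization

Counts are transformed as log10(reads + 1) (base and pseudocount
configurable; the base only rescales the linear fits). For each
non-reference study, ordinary least squares maps its log counts onto the
reference study's over shared targets — same guide, genomic intervals
overlapping within ±2 nt to absorb PAM relocation; at least two shared
targets are required. After calibration the combined cleaved set is
divided by its maximum; values pushed below zero are clamped to 0, and
uncleaved records sit at exactly 0.

## Training-set assembly

Negative mining scans both strands for NGG/NAG motifs, scores the
PAM-anchored windows with the batched kernel, and keeps sites scoring
strictly above 14.75 that do not overlap a known cleaved site of that
guide. The threshold is the complementarity level that ~95% of real
cleaved sites exceed. Guides profiled by several studies are reduced to
the reference study's collection (or the largest collection, with a
warning, if the reference lacks that guide); incompatible studies can be
excluded outright. Each training round bootstraps a guide's positives to
twice their count and draws an equal number of its negatives without
replacement; negatives are re-drawn each round. 100 rounds by default,
with per-round seeds derived from a master seed.

## Ensemble

One `RandomForestRegressor` per round; the score is the mean of member
predictions (spread reported alongside), inheriting the [0, 1] target
range. Defaults: 10 trees per member (the library default of the era the
method was built in, so 100 rounds ≈ 1000 trees total), unlimited depth,
all features per split; everything configurable and recorded in model
metadata, because the original hyperparameters are not documented. A
classification mode (forests on the binary label, scored by
probability) exists and produces very similar rankings; regression is the
default since it preserves graded intensities. Score thresholds are
empirical quantiles over predicted scores of cleaved sites (the 5th
percentile = the score 95% of cleaved sites exceed).

## Cross-validation

Leave-one-sgRNA-out: per fold, alignment parameters are re-optimized on
the training guides only, alignment-derived features recomputed for train
and test, balanced rounds drawn, the ensemble trained, and the held-out
guide scored on its cleaved sites plus an equal-sized random draw of its
uncleaved sites (one draw per fold, fold-seeded). An in-fold audit
asserts by record id that no held-out record reached training.
Leave-study-out holds out a whole study without parameter re-optimization
(mirroring the original protocol) and reports metrics separately for
guides unique to the held-out study versus guides shared with training;
the full multi-study table is harmonized once up front. Negatives are a
shared per-guide pool, so in study mode a common guide's test negatives
could overlap training draws; overlapping ids are removed from the test
set. Pearson r² is computed on the target scale including negatives at 0;
ROC/PRC use the continuous score against the binary label, PRC-AUC by
trapezoidal integration of the precision–recall curve.

The negative-fraction sweep recomputes the per-guide averaged r² while
subsampling each guide's test negatives from 100% down to 0% (positives
only), quantifying how much of the headline number rests on the
class contrast.

## Feature selection and mechanism tests

Forward selection is greedy on pooled held-out r² over guide-level folds.
A full-budget cross-validation per candidate per step is quadratic, so
candidates are screened with a reduced configuration (2 rounds × 10 trees
by default, shared balanced draws across candidates for paired
comparisons); the final importances come from a full-budget ensemble on
the selected set, averaged over members and normalized to sum to 1.

The wobble test forms a (mismatch-count bin) × (wobble / non-wobble)
contingency table over cleaved-site alignments and applies a chi-square
test of independence; bins with expected counts below 1 are folded into
their adjacent neighbor (thinnest bin first), and degenerate tables
raise. The enthalpy test fixes the per-site enthalpies, takes the union
of the <5th and >95th percentile tails, and permutes cleavage frequencies
1,000 times; p = (k+1)/(n+1) where k counts permutations whose tail mean
falls below the observed one — one-sided for *depressed* cleavage at the
extremes, add-one smoothed so p is never zero.

## The synthetic-data generator

The generator emulates the structure of a multi-study off-target
compendium at desk scale: an i.i.d. genome (default 300 kb, GC 0.41),
five guides, 100 cleaved sites per guide planted with a mismatch-count
distribution averaging ≈3.3 (matching the realigned real-data average),
bulges in 18% of sites, NGG:NAG ≈ 9:1, plus 250 uncleaved decoys per
guide carrying 3–5 mismatches so they clear the mining threshold while
overlapping the weak end of the positives. Latent intensity is a
logistic in alignment score (dominant, weight 2.5 on a (score−17.5)/2.5
scale) with weak GC and enthalpy-extremity effects; the reference study
observes `3.5 × (0.2 + 0.8·latent)` log10 reads plus Gaussian noise
(sd 0.25), and each additional study reports a linear rescaling of the
latent intensity. Two modeling choices deserve emphasis: the logistic
effect model is a stand-in for the unknown biological response (chosen so
parameter recovery has a known truth), and measurement noise is attached
to the reference assay so the planted (slope, intercept) of other studies
is the exact OLS estimand; the 0.2 intensity floor mimics assays only
reporting sites above their detection limit and keeps low-count rounding
from censoring the calibration fit.

What passing tests on these fixtures shows: the machinery (alignment,
mining, harmonization, balancing, training, fold hygiene, statistics) is
correct, and planted signal of realistic shape is recovered. What it does
not show: real-data effect sizes, chromatin/annotation effects (the
generator plants none), sequencing error, or cell-line genome divergence
from the reference.

## Problem sizes and numerical choices

The test suite and the acceptance script run the five-guide default
simulation (500 positives, ~1,400 mined negatives), 100-round ensembles of
10 trees, an 84-point penalty grid per fold, and 1,000 replicates for the
statistical-calibration checks — sizes chosen so a complete run finishes
in minutes on one CPU while every component operates at its default
configuration. Alignment scores are compared after rounding to 9 decimals
to make tie-breaking robust to float noise; the batched kernel uses
float32 with a −1e30 sentinel for infeasible states; forests run
single-threaded for reproducibility; all seeds derive from a single master
seed via `numpy.random.SeedSequence`, with CRC32 of a fold tag (not
Python's randomized `hash`) keying per-fold seeds.

## Known limitations

- Genomes are held in memory and scanned exhaustively; fine for
  bacterial-scale or regional scans, not for a seeded whole-human-genome
  search (an index-backed approximate search is deliberately out of
  scope).
- The published per-site compendium is not bundled, so the
  reproduction checks of published realignment/benchmark numbers require
  the user to supply those tables under data/external/; the two
  corresponding acceptance tests report failures otherwise.
- Annotation and DNA-shape features are consumed from user tables, never
  derived from raw assays; absent tables mean those features are inert
  (imputed constants plus missingness indicators).
- The leave-study-out protocol shares the mined negative pool between
  training and test guides, as in the original design; its metrics for
  common guides are correspondingly optimistic.
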