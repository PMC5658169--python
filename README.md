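# casprop

Bulge-aware machine-learning prediction of CRISPR-Cas9 cleavage propensity.

## The problem

Cas9 guided by a 20-nt sgRNA spacer cleaves its intended genomic target —
and, with imperfect complementarity, unintended off-targets. Genome-wide
break-profiling assays (GUIDE-seq, HTGTS, BLESS) showed that off-targets
can carry many mismatches, single-nucleotide DNA or RNA bulges, and
non-canonical PAMs, and that cleavage also depends on the genomic context
of the site, not just its sequence match. `casprop` is for researchers who
design guides or analyze off-target compendia: it scores the *cleavage
propensity* of a (sgRNA, site) pair on a [0, 1] scale and provides the full
training and analysis machinery behind that score.

## The method

**Alignment.** The spacer is aligned to the site by a global
Needleman–Wunsch-style dynamic program with a hard budget of at most three
single-column indels (bulges); adjacent gap columns are allowed but each
consumes one unit of the budget. Because indels change the window length,
the best score over seven PAM-anchored windows (17–23 nt) is taken. With
match = 1, mismatch = 0, gap = −1.25 the score is

    S = n_match − 1.25 · (n_DNA-bulge + n_RNA-bulge)

and penalty values can be re-optimized on any training set by maximizing
the per-guide mean r² between scores and observed cleavage frequencies.

**Features.** Each pair yields a named vector: alignment score and its
decomposition, per-position mismatch indicators (1 = PAM-proximal),
mismatch chemistry (wobble rG·dT / rU·dG, purine–purine and
pyrimidine–pyrimidine transitions, transversions), PAM type (NGG/NAG/other),
nucleotide identities at informative positions, GC content of site and
flanks, nearest-neighbor duplex enthalpy over a 223-nt window, DNA-shape
descriptors and chromatin annotations via pluggable lookup tables, and
sgRNA folding energy via a pluggable provider. Missing pluggable inputs are
null-flagged (NaN), then median-imputed with missingness indicators at
model time.

**Target and training.** Read counts from heterogeneous studies are
log-transformed and linearly calibrated onto the reference study's scale
over shared targets; the regression target is the calibrated value divided
by the dataset maximum. Uncleaved sites are mined exhaustively from the
genome (NGG/NAG-adjacent windows with alignment score > 14.75). Because
negatives dominate, training uses 100 class-balanced rounds — positives
bootstrapped to 2×, an equal number of negatives drawn per guide — with one
random-forest regressor per round; the propensity score is the member mean.

**Evaluation and inference.** Leave-one-sgRNA-out and leave-study-out
cross-validation (with per-fold alignment re-optimization in the former and
a unique/common-guide split in the latter), a metric suite (r², Spearman ρ,
ROC-AUC, PRC-AUC, RMSE), greedy forward feature selection with importance
extraction, and two mechanism probes: a chi-square test for wobble
enrichment with mismatch load and a permutation test for depressed cleavage
at duplex-enthalpy extremes.

Everything is testable offline through a synthetic-data generator that
plants on/off-targets with controlled mismatch/bulge patterns and emits
multi-study read counts from a known effect model.

## Worked example

`examples/` holds one short script per capability. For instance,
`examples/align_guide_to_site.py` aligns a guide to a site carrying a DNA
bulge and a PAM-proximal mismatch:

```text
guide : GACGTACGTA-CGTACGTACG
site  : GACGTACGTATCGTACGTACC (window 21 nt)
score 17.75: 19 matches, 1 mismatches, 1 DNA bulge(s), 0 RNA bulge(s)
mismatch positions (1 = PAM-proximal): (1,)
```

The unpaired `T` in the site is a DNA bulge: it costs −1.25 but restores
the register, so the gapped alignment (19 + 0 − 1.25 = 17.75) beats any
gapless pairing. `examples/train_and_score.py` then trains an ensemble on a
simulated compendium and prints:

```text
trained 20 members on 150 cleaved / 505 mined uncleaved sites
mean propensity: cleaved 0.411, uncleaved 0.053
thresholds: 95% of cleaved sites score above 0.145 (strict), 50% above 0.299 (lenient)
```

i.e. cleaved and mined-uncleaved sites separate by an order of magnitude in
mean score, and the printed cutoffs translate the continuous score into
strict/lenient binary calls the way practitioners use them.

A thin CLI wraps the same library calls:

```sh
casprop simulate --seed 3 --out sim/
casprop train --records sim/records.csv --genome sim/genome.fasta \
        --reference-study SimRef --out model.joblib
casprop score-pairs --model model.joblib --records pairs.csv --genome sim/genome.fasta
casprop rank-within --model model.joblib --sequence promoter.fasta
casprop mine --guide GACGTACGTACGTACGTACG --genome genome.fasta
```

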