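# Methods

This note documents the modelling choices behind `binburden`: the burden
pipeline itself, the synthetic cohort generator used in place of
controlled-access patient data, and the numerical conventions. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Genome binning

The feature coordinate system is a fixed partition of the 22 GRCh38
autosomes into 5-Mb windows. A chromosome of length L contributes
`ceil(L / bin_size)` bins; bin k covers the closed 1-based interval
`[(k-1)*bin_size + 1, min(k*bin_size, L)]`, so the last bin of each
chromosome is short. With the embedded GRCh38 autosome lengths and the
default `bin_size = 5_000_000` this yields exactly 587 bins. Sex
chromosomes are excluded by default: the 587-bin count is consistent with
autosomes only, and the downstream weight figures span 22 autosomes.
Alternative genomes are accepted as two-column chrom-sizes TSVs; on disk
the bin index is exported as BED (0-based half-open), while all in-memory
coordinates are 1-based closed (the VCF convention). Chromosome names
`"1"` and `"chr1"` are equivalent on input and canonicalized to the
`chr`-prefixed form.

## Variant categories and the MAF filter

Each retained variant receives exactly one of seven consequence classes:
stop-gain, frameshift, nonsynonymous (coding); UTR, ncRNA, intronic,
intergenic (non-coding). Two sources are supported: a precomputed
annotation table (chrom, pos, ref, alt, category), or the built-in
classifier against a supplied gene model (GFF3). The classifier resolves
overlapping annotations with the conventional precedence *coding effect >
UTR > ncRNA > intronic > intergenic*; a variant overlapping no gene is
intergenic. Coding effects are assessed at the codon level against the
spliced CDS sequence (carried as a `cds_seq` attribute in the GFF3 so no
reference FASTA is needed): an SNV creating a stop codon is stop-gain, an
amino-acid-changing SNV is nonsynonymous, and a synonymous SNV belongs to
none of the seven classes and is dropped from feature building.
"Frameshift" is implemented as a length-changing indel in the CDS whose
length difference is not a multiple of 3 — an SNV cannot shift the
reading frame, so the class necessarily refers to small indels. In-frame
indels and same-length MNVs in the CDS are grouped with nonsynonymous
(protein-altering); they are not frequent enough in the intended inputs
to warrant their own class. An inconsistent gene model (CDS base that
contradicts the variant's reference allele, CDS length not a multiple of
3) is an error, not a silent reclassification.

Population-common variants are removed before burden counting: a variant
is dropped iff its folded minor allele frequency `min(AF, 1-AF)` in the
supplied reference panel is strictly greater than the threshold (default
0.05). Variants absent from the panel are retained, and the filter is
idempotent. Multiallelic sites are decomposed to one record per alt
allele; missing genotypes count as non-carriers.

## Burden matrices

For each category, `X[s, b]` counts the retained variant sites in bin `b`
at which sample `s` carries at least one alternate allele
("site-presence", the default — heterozygous and homozygous carriers both
contribute 1). An allele-dosage mode (sum of 0/1/2 dosages) is kept
behind a flag; presence is the standard burden-collapsing convention and
matches counting the *occurrence* of variants. Matrices for different
categories are never merged, because each variant class is trained and
reported separately.

## Feature weights and pruning

Bins are ranked by Gini impurity importance from a
`RandomForestClassifier` with 500 trees, `max_features = sqrt`,
`min_samples_split = 2` and unlimited depth (nodes expanded until pure),
normalized to sum to 1. Impurity importance (not permutation importance)
is the estimator's native relevance measure for this configuration. A
feature never split on has importance exactly 0, so pruning uses an exact
zero comparison — no epsilon. Pruning only selects columns: the reported
weights remain those computed on the full bin set and are *not*
renormalized over the survivors, so hotspot percentages always refer to
the full 587-bin (or mini-genome) distribution. In the degenerate case
where no tree ever splits (constant features), the weights fall back to
uniform so the sum-to-1 invariant holds unconditionally.

Within the shuffle-test protocol, feature selection is refit on each
round's training fold only; test samples never influence it. The
descriptive hotspot report is the one place a full-cohort fit is used.

## Classifiers

Both tasks use scikit-learn's `MLPClassifier`. The binary task separates
samples with any diagnosis from controls. The multi-label task trains a
single network with 8 sigmoid outputs (native multi-label mode, not
one-vs-rest) on the patients with at least one diagnosis, and thresholds
each output at 0.5; no consistency between columns is enforced. A label
column constant in training is warned about and predicted constant. No
class rebalancing is applied; accuracy is the plain fraction correct.

Hyperparameters (1-3 hidden layers; 16-256 neurons per layer,
log-uniform; relu/tanh/logistic; adam/lbfgs/sgd; L2 alpha 1e-6-1e-1,
log; max_iter 200-2000; initial learning rate 1e-4-1e-1, log) are chosen
by a seeded random search with a default budget of 30 evaluations scored
on a 20% inner validation split of the training fold. The contract is
"best configuration of the budget", deterministic given the seed;
candidates whose fit raises are skipped. By default the search runs once
on the first round's training fold and the winning configuration is
reused across rounds (`reoptimize_per_round` re-runs it every round);
re-optimizing per round multiplies cost ~budget-fold for little gain on
the smooth burden features.

## Evaluation protocol and metrics

Each round r of the two-fold shuffle test draws a random permutation with
seed `base_seed + r`, takes the first half as the training fold and the
rest as the test fold (1:1 up to one sample), and trains/evaluates in one
orientation only. A round whose training fold lacks both classes is
resampled once, then the run fails. Eligibility per task: everyone for
case-control; patients with exactly one diagnosis plus all controls for
single-diagnosis-vs-control; the >= 1-diagnosis patients for multi-label.
Metrics are summarized as mean +- sample SD (ddof = 1) over rounds.

Hamming loss is the fraction of the `m x 8` label cells predicted
incorrectly; exact match is the fraction of rows predicted perfectly
(chance level `(1/2)^8 = 1/256` for uniform guessing); per-label
precision `TP/(TP+FP)` and recall `TP/(TP+FN)` are reported per disorder,
with zero-denominator values reported as 0 and flagged. The union bound
`exact_match >= 1 - 8 * hamming_loss` holds on every evaluation. For the
multi-label task the random-forest feature selection needs a single
target, so the 8-label matrix is encoded as a label powerset (one class
per distinct 8-bit pattern, up to 256 classes).

## Synthetic cohort generator

The generator emulates the study conditions: a cohort with a ~1:2
case:control ratio (defaults 1384 cases, 2795 controls, scalable), eight
correlated binary diagnoses, seven variant categories spread over 5-Mb
bins, a MAF spectrum containing common variants, and case-enriched effect
bins with known locations.

**Burden model.** Per sample, bin, and category, the carried-site count
is Poisson with rate `lambda * rho^(case AND effect bin)`;
`lambda = 3.0` per bin per category by default, a burden scale at which
a handful of bins carry usable signal without trivializing the task.
Carried sites are drawn without replacement from a fixed pool of 40
candidate sites per (bin, category), engineered against the synthetic
gene model (one two-exon coding gene with split CDS and one single-exon
ncRNA gene per bin): designated CDS codons yield stop-gains (`CGA->TGA`)
and nonsynonymous changes (`GCT->CCT`), frameshift sites are 1-bp
insertions in the CDS, and UTR/ncRNA/intronic/intergenic sites sit in the
matching intervals. This makes the VCF round trip *bit-exact*: re-reading
the generated VCF through classification, MAF filtering and burden
counting reproduces the generator's count tensors cell for cell. About
10% of carriers are homozygous so the dosage mode is exercised. Trailing
bins narrower than ~450 kb receive no sites (their burden is
structurally zero).

**Effect presets.** `rho` presets are null 1.0, weak 1.15, medium 1.3,
strong 1.4, with 3 effect bins planted per coding category by default
(mirroring the coding-hotspot pattern). The strong preset is calibrated
so that a 20-round two-fold shuffle on a 200/200 cohort lands at ~0.6-0.7
binary accuracy — the working range of burden classifiers of this type —
which makes "signal clearly above chance but far from perfect" the
regime the tests probe. Optional per-label rate multipliers
(`label_effects`) let specific diagnoses modulate effect-bin burden.

**Labels.** Cases draw the 8 diagnoses from a liability-threshold model:
one shared standard-normal factor per case with loading 0.6 plus
independent noise, thresholded at per-label prevalences (0.55, 0.35,
0.40, 0.25, 0.20, 0.12, 0.12, 0.15 in the fixed label order) chosen to
mirror the typical ordering in pediatric cohorts (ADHD most common;
ODD/autism smallest). The shared factor induces comorbidity — most cases
carry 1-4 diagnoses, a few up to 6-8 — and the mean number of diagnoses
rises monotonically with the loading. Every case is forced to carry at
least one diagnosis; controls carry none.

**Common variants.** A configurable number of intergenic sites (default
50) are planted with panel AF drawn uniformly from 0.10-0.50 and
Hardy-Weinberg carrier probabilities; they appear in the VCF and the AF
table but not in the truth counts, so the MAF filter must remove exactly
this set. A further ~10% of rare signal sites receive panel AF <= 0.05 to
exercise the "present in panel but rare" path.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and a realistic site
frequency spectrum, relatedness and population structure, sequencing or
genotyping error, gene-density variation across bins, and any true causal
architecture of psychiatric disorders. The round-trip and recovery tests
validate the *pipeline's correctness and statistical calibration*, not
the biological claim.

## Problem sizes

Desk-scale defaults keep every run cheap: the mini-genome
(4 chromosomes x 25 Mb = 20 bins) and 200/200 cohorts for shuffle tests
and recovery sweeps (20 rounds / 20 seeds, 500 trees), and the full
GRCh38 partition wherever only the bin arithmetic matters. The full suite
runs in a couple of minutes on one CPU, as does the acceptance script.
Study-scale runs (587 bins, 4179 samples, 50 rounds) use the same code
paths through the YAML pipeline config.

## Numerical conventions and degenerate inputs

- Weight sum checked to 1e-9; weights non-negative by construction.
- Ties in the weight ranking are broken by bin order (stable sort);
  hotspot calls use a strict `> threshold` comparison (default 1%).
- Dispersion summaries use population SD (ddof = 0) of the weight vector,
  which is a fixed-length distribution rather than a sample.
- Mean +- SD over shuffle rounds uses sample SD (ddof = 1).
- Empty test sets predict empty; a constant binary training target
  collapses to a constant predictor with a warning.
- All seeds are explicit; derived seeds stay below 2^31.

## Known limitations

- The built-in classifier handles SNVs and small indels only; no
  splice-site class (not among the seven categories) and no
  protein-consequence prediction beyond stop/frameshift/nonsynonymous.
- Random hyperparameter search explores the same space a model-based
  optimizer would, but with a fixed budget it may select a slightly
  weaker configuration on rugged objectives.
- `single_diagnosis_vs_control` keeps the full control set, so its folds
  are class-imbalanced when cases are few; accuracy should be read
  against the majority-class rate.
- GFF3 support covers the gene/mRNA|ncRNA/exon/CDS subset the pipeline
  needs, not arbitrary annotation files.
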