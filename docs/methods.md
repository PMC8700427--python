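# Methods

This note documents the models, rules and numerical choices behind
`somamut`, what the synthetic-data generator does and does not emulate, and
the known quirks of the bundled data.

## Pathogenicity rules

A coding, non-silent variant is classified on three levels:

1. **Potentially pathogenic** — truncating classes: nonsense, frameshift,
   and splice-site variants within ±3 bases of the exon boundary. The ±3
   window (rather than the conventional ±2) follows the curation rule the
   bundled driver tables were built with; the offset is taken on either
   side of the boundary, and a splice-site record with no recorded offset is
   treated as canonical (it was already annotated as a splice change).
   Predictor votes are ignored for truncating variants.
2. **Possibly pathogenic** — missense variants called pathogenic by at
   least 3 of the 5 effect predictors (SIFT, PolyPhen-2, FATHMM,
   MutationTaster, MutationAssessor), or by at least 1 of 5 when the gene is
   a Cancer Gene Census (CGC) gene, tier 1 or tier 2 alike.
3. **Benign** — everything else, including in-frame indels and other coding
   classes the rules do not name.

**Missing predictor verdicts** count as non-pathogenic votes and the
denominator stays 5. The source rules say "3 out of 5" / "1 of 5" without a
missingness policy; holding the denominator fixed is the conservative,
reproducible reading (a variant with two pathogenic calls and three missing
slots is not promoted). `votes_available` is reported so downstream users
can see how much evidence a call rests on. Tie-break order: truncating
dominates both vote rules; when both vote rules hold, the 3-of-5 rule is the
one recorded.

These rules are exhaustively checked against an enumerated truth table over
all 3⁵ vote patterns × census status × variant class, plus monotonicity
(adding a pathogenic vote, or granting census membership, never demotes a
verdict).

## Driver profiles and combination categories

Only potentially/possibly pathogenic variants in CGC genes populate a
sample's role sets (oncogene / TSG / dual role, the census "oncogene/TSG"
annotation kept as a distinct value). A sample is a **combination** when an
affected oncogene co-occurs with an affected TSG, counting dual-role genes
for either side: OG+TSG, OG+dual, TSG+dual, or at least two dual-role genes.
**cgc_alone** means exactly one affected census gene (however many variants
it carries); **no_cgc** means none, and only then are CCGD rank-A genes with
pathogenic variants reported as putative drivers.

These three categories do not partition real data: a sample can carry two
or more affected genes that are all oncogenes or all TSGs, which is neither
a combination nor a single-gene sample. The package therefore adds a fourth
explicit category, **same_role_only**, and the invariant "categories
partition the cohort" holds over the four. (In the bundled elderly-HGSOC
table exactly one sample lands there, which is why the published breakdown
sums to 59/60.)

**Benign exceptions.** Curated census genes whose observed variants were
judged non-pathogenic are excluded from profiles. Two mechanisms exist:
a per-cohort gene list (`exceptions_*.tsv`, the configuration interface) and
per-occurrence `b` marks inside driver-table fixtures. The bundled tables
use occurrence-level marks because the same gene can be benign in one sample
and pathogenic in another (KIT and FAT1 both occur each way in the elderly
HGSOC table; gene-level exclusion would change the combination count).

**Pathway scans.** Ras/PIK3CA membership: AKT3, BRAF, HRAS, KRAS, MAP2K2,
MAPK1, MTOR, NF1, NF2, NRAS, PIK3CA, PIK3CB, PIK3R1, PTEN, RAC1, RAF1,
RANBP2 — the union of the genes the source study itself enumerates per
cohort; PREX2 (a RAC1 regulator) is deliberately not a member, matching the
study's own per-cohort counts. The DNA-repair list was assembled from the
repair genes the study names plus canonical pathway members (HRR, MMR, NER,
BER, translesion/polymerase, checkpoint); no authoritative list was printed,
so membership is a documented free parameter of the package. TP53 is on the
list as a checkpoint gene but never counts as a repair hit; repair scans
include non-census repair genes.

## Spectra and the 96-context matrix

SNVs are strand-normalised so the reported reference base is a pyrimidine:
purine references are reverse-complemented together with their
trinucleotide context. The 96 context classes are ordered lexicographically
by (substitution class, 5' base, 3' base) — `A[C>A]A … T[T>G]T` — and this
order is shared by the bundled reference matrix, so matrices are comparable
across runs. Contexts come from the annotation column (Oncotator-style
`ref_context`, centred automatically when longer than 3); SNVs without a
resolvable context, or whose context centre contradicts the reference
allele, are dropped and tallied in QC counters. Only SNVs feed the spectra;
indels count toward coding-variant burdens but not contexts (the standard
convention for signature analysis).

## Signature extraction

The samples' 96-context counts V (96 × n) are factorised V ≈ WH with
multiplicative-update NMF under the Kullback–Leibler objective
(scikit-learn's `mu` solver), the classical formulation for mutational
signatures. Design choices:

- **Restarts:** 10 random initialisations per candidate rank by default;
  the lowest-error restart is kept. Seeds for restarts are drawn from a
  single user seed, so runs are deterministic.
- **Rank selection:** for each candidate k a stability score is computed —
  the mean cosine of optimally matched profile columns (Hungarian
  assignment) over all restart pairs. The chosen k is the smallest whose
  stability reaches 0.8; if none does, the most stable k is used with a
  warning. Reconstruction error and stability per k are reported.
- **Normalisation:** W columns are scaled to unit sum with the compensating
  factor folded into H, so W columns are probability profiles and H carries
  the mutation counts. Exposures are reported as per-sample fractions.
- **Matching:** each extracted profile is matched to the reference column
  with the highest cosine similarity (greedy, per column). The assignment
  is deliberately not forced to be injective — two extracted profiles
  hitting the same reference is a real diagnostic — and duplicates plus
  matches below a configurable floor (default 0.75) are flagged.
- **Attribution:** each sample is labelled by the matched reference index
  of its largest exposure; exact ties resolve to the lowest reference index
  and are logged. Per-group tables report the percentage of samples
  dominated by each signature. Dominant-exposure attribution is a choice:
  published per-group signature percentages rarely state their attribution
  rule, so these percentages are comparable only in trend. A non-default
  refit mode (`signatures.refit_exposures`) fits each sample against the
  full reference catalogue by non-negative least squares instead of using
  the de-novo factors, for settings where the catalogue is trusted and
  discovery is not the goal.

**Reference catalogue.** The bundled 96×30 matrix
(`data/signature_reference_synthetic.tsv`) is a synthetic construction, not
a published catalogue: six structured columns emulate the qualitative
shapes of well-known processes (1: C>T at NpCpG; 2: C>T at TpCpN; 3:
near-uniform; 5: T>C-dominated; 6: C>T at GpCpN; 13: C>G at TpCpN) and the
remaining 24 are seeded Dirichlet draws kept below cosine 0.70 to every
structured column. Its generation is deterministic
(`somamut.reference.build_reference_matrix`) and a test asserts the bundled
file regenerates bit-identically. All signature tests are therefore
*parameter-recovery* statements against this catalogue; matching against
the real COSMIC v2 matrix requires passing it via `--cosmic`.

The recovery study run by the acceptance suite uses 40 samples × ~2000
mutations per sample, mixtures of the signature-1- and signature-3-like
columns, 20 seeded replicates, and requires a median matched cosine ≥ 0.9.
At smaller scales the near-flat column is only partially identifiable (it
absorbs part of any co-occurring process), which is why the reduced-scale
unit test asserts a looser 0.85 bound — a property of flat signatures, not
of the solver.

## Statistics

- **Mann–Whitney U**, two-sided: exact enumeration when both samples are
  ≤20 and tie-free, otherwise the normal approximation with tie correction.
  A constant pooled sample returns p = 1 with a warning. Exactness is
  verified against full permutation enumeration for n+m ≤ 12.
- **Fisher's exact test**, two-sided by the probability-mass ordering rule
  (summing hypergeometric probabilities ≤ the observed table's). This is
  the dominant convention but not the only one; published p-values computed
  under another convention (or from counts that differ from the printed
  tables) will not reproduce exactly. Agreement with brute-force
  enumeration is verified to 1e-12 for tables with N ≤ 60.
- **Calibration:** under identical generating distributions at the bundled
  study's group sizes (21 vs 60), both tests' type-I error at α = 0.05 is
  required to sit inside the 95% binomial band over 1000 seeded replicates.
- No multiplicity correction by default (matching how such per-gene
  contrasts are usually reported); Benjamini–Hochberg is available behind
  the `adjust` flag.
- **TP53 stratification:** `stats.tp53_stratified_comparison` contrasts
  per-sample coding-variant burdens between TP53-affected and TP53-wild-type
  samples (affectedness keyed on driver profiles) with the same
  Mann–Whitney machinery.

## Synthetic cohorts

`somamut.simulate` draws, per sample: a mutation count from a log-normal
(default μ = 4.0, σ = 0.5 on the log scale, i.e. a median of ~55 coding
mutations — the scale of exome studies in these tumor types); 96-context
classes from the group's signature mixture; and a uniformly random rendering
strand, so the pyrimidine normalisation is genuinely exercised. Passenger
mutations land in a synthetic non-census gene pool (`BG0000`…) with
length-weighted sampling (Zipf-like weights), giving recurrence ranking the
FLAGS-like long-gene behaviour without a genome. Driver spikes are injected
per group with per-sample probabilities and chosen variant classes;
predictor verdicts are sampled conditionally on the latent truth class
(defaults: pathogenic vote probability 0.95 per predictor for drivers, 0.05
for passengers). Contamination rows (silent/non-coding) are added per row
with the configured probability. Identical seed and spec give byte-identical
files.

What the generator does **not** emulate: genomic coordinates, transcript
structure, mutational hotspots, copy-number or structural variation,
germline leakage, inter-predictor correlation, and sample purity. Passing
tests on synthetic cohorts therefore demonstrate the pipeline's
correctness and statistical calibration under the stated generative model,
not robustness to annotation noise in real call sets.

## Bundled driver tables and their quirks

The four driver-table fixtures encode a published per-sample driver
comparison (young/elderly HGSOC and TNBC; 21/60/86/23 samples) verbatim:
gene symbols as printed (including obvious typos, kept deliberately), the
OncoKB effect glyph per occurrence (`++`, `+`, `--`, `-`, `*`, `?`), and
`b` for occurrences judged benign. Encoding benign marks per occurrence
reproduces the published combination breakdown exactly (14/21, 51/60,
62/86, 23/23 combinations; 5 and 6 single-census samples in HGSOC; 2/21,
2/60, 6/86, 0/23 with no census gene; TP53 in 14/49/60/17 samples; KMT2C in
6 elderly-TNBC samples; 3 and 9 Ras-pathway samples and 4 and 12
repair-gene samples in HGSOC).

Two source inconsistencies are worth knowing:

- The young-TNBC table yields **18** samples with exactly one affected
  census gene under the stated rule, while the source text reports 12 (its
  own enumeration sums to 11–12 and omits genes the table contains, e.g. a
  pathogenic TET2 single). No assignment of benign marks can reconcile 12
  with the published combination (62) and no-census (6) counts, so the
  package reports the recomputed 18 and the corresponding acceptance check
  is expected to disagree with the printed value.
- The elderly-HGSOC TP53 count is 49/60 (81.7%) from the per-sample table
  and one summary sentence, but 50/60 (~83%) in a separate summary table;
  the per-sample table is taken as ground truth.
- Percentages are reported rounded to one decimal (14/21 → 66.7%), even
  where the source truncated (66.6%).

## Problem sizes

Tests and the acceptance suite run at the sizes stated above: full 3⁵ × 2
rule enumeration; Fisher enumeration over a sweep of N ≤ 60 tables;
Mann–Whitney permutation oracle at n+m ≤ 12; 1000-replicate null
calibration at group sizes 21 vs 60; signature recovery at 40 samples ×
2000 mutations × 20 replicates; pipeline end-to-end runs on 10–24-sample
synthetic cohorts. The whole suite completes in well under a minute on one
CPU.
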