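# Methods

This note documents the models, conventions and numerical choices behind
tcrspec, in the order data flows through the pipeline.

## Clonotype calling

A contig survives when it is full length and productive. When a cell
carries more than one surviving contig for a chain, the default keeps the
one with the most UMIs (ties broken by lexicographically smallest CDR3),
mirroring the upstream assembler's convention; `multichain="drop"`
discards such cells instead. The two rules differ by at most the small
multi-chain fraction of cells, which is why pairing rates between
pipelines can disagree by a percent-level margin. Cells, not UMIs, are
the unit of clone size: a clonotype is the set of cells sharing identical
CDR3α and CDR3β amino-acid strings, and its size is its number of unique
barcodes. V/J genes are taken verbatim per contig (an optional normalizer
trims `*01`-style allele suffixes); the clonotype records the modal usage
over its members.

## Diversity, rarefaction, ordination

Shannon diversity uses the natural log (ecology convention). Rarefaction
is analytic rather than resampled: the expected richness at subsample
size m is Σᵢ (1 − C(N−nᵢ, m)/C(N, m)), evaluated with log-gamma for
stability; Monte-Carlo subsampling is retained only as a test oracle.
The default step is 20 cells and the curve always includes m = N.

NMDS minimizes Kruskal stress-1 by SMACOF majorization with monotone
(isotonic) regression, best of 50 random restarts by default, seeded and
deterministic. The reported stress is recomputed from the winning
configuration; stress ≥ 0.1 raises a warning and clears the `converged`
flag, the conventional bar for a trustworthy ordination. The sample
ordination runs on Bray–Curtis dissimilarities of raw per-sample counts
restricted to public clonotypes; a presence/absence matrix can be passed
instead, since which of the two the original analysis used is not
determinable. Bray–Curtis between two all-zero rows (a sample carrying no
public clonotypes) is defined as 0.

Expansion labels use log₂((b + 1)/(a + 1)): the pseudocount of 1 on both
sides keeps zero counts finite and the labeling antisymmetric under
condition swap. Defaults: |log₂FC| > 3 with clone size > 10 for
clonotypes, |log₂FC| > 2.5 with total size > 10 for specificity groups —
both configurable.

## Specificity grouping

Local similarity works on the CDR3β interior after trimming 3 N-terminal
and 2 C-terminal residues (the conserved stem). k-mers of length 2–4 are
counted; enrichment is tested by default for k ∈ {3, 4} (2-mers are too
degenerate to be informative) with a one-sided Fisher exact test on
unique-CDR3 counts of query versus a reference repertoire, implemented as
the hypergeometric survival function. Motifs with p < 10⁻³ seed groups;
membership is by containment of the motif in the trimmed interior, and a
clonotype may join any number of groups. Global similarity joins
same-length CDR3βs at Hamming distance ≤ 1 whose single substitution has
BLOSUM62 ≥ 0; connected components spanning ≥ 2 sequences (counting
duplicates) form groups.

V-gene bias and length concentration are one-sided Fisher tails for
over-representation of the group's modal TRBV gene (respectively modal
CDR3β length) among members versus the full repertoire. The final score
is the product motif_p × vgene_p × length_p. This composition is a
design choice: it makes the 10⁻⁵ threshold interpretable as a joint
significance, but it is not a numerical replica of GLIPH2's published
score, and results should not be expected to match GLIPH2 output
byte for byte. Global-cluster groups carry motif_p = 1, so in practice
the final-score filter selects motif-seeded groups.

The default filter — ≥ 4 unique clonotypes from ≥ 3 samples, V-bias
p < 0.05, final score < 10⁻⁵ — follows the stricter of the two published
phrasings; the ≥ 4-*samples* variant is reachable via `min_samples`.

An optional non-templated-motif bonus (ranking weight 2) flags motifs
whose codons fall outside the germline V prefix / J suffix of the CDR3
nucleotide sequence; it requires nucleotide input plus germline segments
and is off by default. It reweights ranking only, never p-values.

## Reference database and annotation transfer

Raw exports are harmonized by per-source column maps; CDR3s with
characters outside the 20 amino-acid letters are dropped, then exact
duplicate rows (the same row from the same source) are removed — the same
(cdr3b, peptide) from two sources is deliberately kept twice. Disease
class comes from an editable lookup with fallback `other`. Species
filtering is off by default, since cross-species CDR3β matching is part
of the intended use. Compilation is idempotent.

Exact matching attaches every (peptide, antigen, disease class) of a
database CDR3β identical to the clonotype's. Motif transfer matches a
query group's seed motif against motif groups built on the database
itself (same trimming and k-mer convention, ≥ 3 distinct CDR3s per
motif) and inherits the majority annotation by unique database CDR3
count; exact ties attach all tied annotations with an ambiguity flag.

## PWM proteome scan

Training peptides are the 9-mers annotated to clonotypes with clone size
strictly greater than 3 whose log₂FC sign matches the requested
condition. The weight is clone size × fold enrichment with fold
enrichment on the linear scale, 2^|log₂FC|. Weights are rescaled to mean
1 before the pseudocount (0.01 per cell) is applied, which makes the PWM
exactly invariant under global weight rescaling — only weight ratios
matter. Entries are positional frequencies divided by a background
composition (uniform by default; the pipeline passes the scanned
proteome's own composition). A 9-mer scores the log-sum of its positional
ratios, equivalently the log product of enrichment ratios.

Significance is empirical over the realized null of all proteome windows:
p = (number of windows scoring at least as high)/n_windows, ties sharing
the larger rank, so the unique best window has p = 1/n_windows.
Bonferroni = min(1, p·n_windows) follows; note that under this null the
top hit's Bonferroni value is 1 by construction, so ranking and raw p
carry the information. An alternative null from column-shuffled PWMs is
available behind `p_mode="shuffled_pwm"`. Windows containing letters
outside the 20-letter alphabet are skipped.

## Expression linkage

Cells join clonotypes by (sample, barcode), with an optional normalizer
stripping 10x `-1`-style suffixes. Normalization is ln(1 + 10⁴·count /
cell total); raw counts are kept for per-entity average expression.
Spearman correlations use average ranks for ties; constant genes are
reported as ρ = 0 with a degeneracy flag rather than NaN. Strata with
fewer than 10 matched cells are skipped.

Differential expression is a two-sided Wilcoxon rank-sum test per gene
with Bonferroni adjustment — a deliberate stand-in for hurdle-model
testing, chosen because the rank-sum test is assumption-light and its
power and calibration are verifiable on synthetic data; DE output here is
validated on that basis, not on reproducing any published gene list.
log₂FC is the difference of mean log-normalized expression in base 2.

Module scores follow the binned-control construction: genes are ranked by
average expression into 24 bins and each gene-set gene draws 100 controls
from its bin with a seeded generator; the score is mean(set) −
mean(pooled controls), so an incoherent set scores near zero.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study's design parameters: 5 + 5 samples in
two conditions, discrete power-law clone sizes (inverse-CDF on a
truncated Zipf, exponent 2.5, cap 50 — reproducing the heavy tail without
fitting), 8 public clonotypes emitted in both conditions, planted 2–4-mer
CDR3β motifs at 5% carrier fraction placed strictly inside the trimmed
interior, carrier V-gene bias of 0.9 toward a per-motif dedicated TRBV
(real specificity groups share V usage; without this the V-bias filter
would be unsatisfiable by construction), negative-binomial expression
with dispersion 0.5, and planted genes whose log-mean is base ±
effect × log(clone size) or shifted by condition. Decoy cells are
per-cell Bernoulli draws emitted as unpaired TRA-only contigs. The
reference database plants each motif's carriers and extra motif-bearing
entries annotated to a known 9-mer peptide, plus deliberate duplicates
and invalid rows; the proteome plants those peptides at recorded
positions.

Not emulated: VDJ recombination statistics, sequencing or UMI error,
doublets, batch effects, cluster structure in expression (cluster labels
are drawn at random), or realistic V/J usage distributions. Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted signal under the stated noise model — not
performance on the full complexity of real data.

A note on calibration: when planted size-correlated genes are present,
counts-per-total normalization makes *null* genes compositionally
(anti-)correlated with clone size; this is a property of normalized data,
not an artifact of the estimator. Null calibration is therefore asserted
on the zero-effect model, where every gene is genuinely null.

## Problem sizes and determinism

The test suite and acceptance script run the study at 150–300 clonotypes
per sample (1,500–3,000 clonotypes, roughly 2,500–6,000 cells), 60–200
genes, and proteomes of 10⁴–3×10⁴ windows — sizes at which every planted
signal is comfortably detectable and the full suite completes in about a
minute. All randomness flows from explicit seeds through
`numpy.random.Generator`; identical configuration yields byte-identical
artifacts, verified by SHA-256 checksums in the run manifest.

## Known limitations

- The final-score composition and the non-templated bonus are
  approximations of GLIPH2's undocumented internals; thresholds carry the
  published defaults but scores are not comparable across tools.
- Exact-match annotation is case- and allele-sensitive on CDR3 strings
  only; V-gene concordance is not required for a match.
- The empirical all-windows p-value is granular at 1/n_windows and the
  derived Bonferroni value saturates at 1 for top hits.
- Differential expression ignores donor/sample structure
  (pseudo-replication is the caller's responsibility via stratification).
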