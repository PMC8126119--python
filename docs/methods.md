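# Methods

## Scope and data model

The pipeline consumes aligned reads (SAM), a genome (FASTA) and a gene
annotation (GFF3) and works gene-wise: all isoforms of a `gene_id` are
collapsed into a single transcript model whose CDS intervals are
union-merged and whose 5'UTR comes either from the annotation or from a
merge of published 5'UTR sources (per gene, the source with the greatest
total UTR length wins; ties keep the earliest source in the user-supplied
order, which makes the merge deterministic and idempotent). GFF3
coordinates (1-based closed) are converted to 0-based half-open internally.
Genes whose CDS length is not a multiple of three, or whose CDS does not
start with ATG, are flagged but never dropped. Codons containing N never
match ATG or a stop.

## uORF discovery

A uORF is any ATG whose nearest in-frame stop codon lies fully inside the
5'UTR, in any frame; nested and overlapping candidates are all reported and
left to read-count filters. "Size" counts start through stop codon
inclusive, so the default `min_codons = 10` means peptides of ≥ 9 amino
acids. ATGs with no in-frame stop before the CDS are excluded: such ORFs
would overlap the main CDS and their footprints would be ambiguous.
Near-cognate starts are supported behind an off-by-default flag.

## Read counting and P-sites

Whole-read counting reproduces htseq-count semantics with `-a 0 -t exon -i
gene_id`: `union` (used for CDS) assigns a read to the union of genes
overlapping any aligned base; `intersection_strict` (used for 5'UTRs, to
exclude ribosomes sitting on the first CDS codons) intersects the gene sets
covering every aligned base, so any uncovered base forces `no_feature`.
A result set of size one is an assignment; larger sets are `ambiguous`.
Ambiguous and unassigned reads are excluded from feature counts but kept in
the library size (total mapped reads), which is the CPM denominator.
Secondary and supplementary alignments are skipped; the MAPQ filter is
applied before assignment and tallied separately, so per-sample tallies
(`assigned + ambiguous + no_feature + low_mapq`) always reconcile with the
record count.

Ribo-Seq P-sites are placed at a fixed offset from the footprint 5' end:
position `start + offset` on the plus strand, `(end − 1) − offset` on the
minus strand. The offset table defaults to 12 nt for 28–30-mers — the
standard yeast footprint convention — and is fully configurable; reads
whose length has no entry are skipped and tallied. uORF occupancy is
counted by P-site containment (a point, not the read span), split by frame
relative to the uORF's own ATG: frame 0 is in-frame (f1).

## Translation score

RibORF-style classifiers combine 3-nt periodicity with homogeneity of the
signal along the ORF; the trained weights of the published SVM are not
reproducible, so the score here is a transparent deterministic combination
of the same two features:

* periodicity `p* = max(0, (f1/(f1+f2+f3) − 1/3) / (2/3))` — the in-frame
  fraction rescaled so chance level (1/3) maps to 0 and perfect
  periodicity to 1;
* homogeneity `PME = H / Hmax`, the Shannon entropy of in-frame per-codon
  counts relative to uniform (any log base; natural log used). PME is 0
  for a single pile-up, 1 for perfectly even coverage, and a `no_signal`
  sentinel with score 0 when there are no in-frame reads;
* `score = sqrt(p* × PME)`, a geometric mean in [0, 1], invariant to
  uniform scaling of counts.

Selection uses the conventional 0.7 cutoff (strict), pooled reads across
all samples ≥ 10, and length ≥ 10 codons. Whether 0.7 on this scale equals
0.7 on an SVM's scale is unknowable; the contract is calibration on planted
truth: with in-frame probability 0.85 and ≥ 30 reads ≥ 90% of uORFs exceed
0.7, at chance periodicity ≥ 95% do not (both hold with margin, see
`scripts/acceptance.py` output).

## Quantification

CPM = 1e6 × count / library size. Replicates are averaged on the CPM scale
(arithmetic mean) before any ratio. The coverage filter keeps a gene when
its replicate-averaged raw count reaches 10 in at least one condition;
ratio analyses use the filter per assay, TE uses it in both assays. After
filtering, zero cells get a 0.5-read pseudocount so logs stay finite — at
the 10-read threshold the induced bias is negligible. The global
5'UTR:CDS shift sums raw counts over genes within each condition,
`(ΣUTR_s/ΣCDS_s) / (ΣUTR_n/ΣCDS_n)`, which cancels sequencing depth
exactly; we sum raw counts rather than CPM (the two differ only through
per-sample depth weighting of genes).

Because CPM divides by total mapped reads, all fold changes are relative
to the sample's composition: a multiplier planted on every gene is
invisible, and planted effects are recovered only up to a pool-wide
constant. Recovery tests therefore centre estimates on the pool median.
At the default noise level (NB dispersion 0.1, 3 replicates) the per-gene
log2FC estimate carries an SD of ≈ 0.37 log2, i.e. a median absolute error
around 0.25 — the statistical floor any recovery assertion must respect.

## Differential expression and regulatory classes

Both assays' CDS tables are subsampled to a common depth (multivariate
hypergeometric per sample, exact column sums, seeded), so the assay with
more reads does not dominate power. TMM factors follow the edgeR
definition — M/A values against a reference column chosen by
upper-quartile proximity to the mean, genes with zeros excluded, 30%/5%
two-sided trims on M and A, inverse-delta-variance weighting, geometric
mean 1 — and the implementation is tested to 1e-8 against edgeR's
`calcNormFactors` via Rscript.

The per-gene test is an explicit voom-style procedure: log2-CPM with a
0.5-count offset; an unweighted two-group fit; a lowess trend (span 0.5) of
sqrt-residual-SD against mean log-count; observation weights 1/trend⁴
evaluated at fitted log-counts; a weighted two-group fit; and
empirical-Bayes shrinkage of residual variances using the standard
log-scale moment estimator of the scaled-F prior (trigamma inversion by
Newton's method), giving moderated t statistics on `df_residual +
df_prior` degrees of freedom, BH-adjusted. Numerical identity with limma
is not claimed; the contract is calibration: on null NB simulations (2000
genes, 3v3, dispersion 0.1) the fraction of p < 0.05 stays within
[0.035, 0.065] per seed.

Significance for classification is adjusted p < 0.05 AND |log2FC| above
one sample SD of the assay's log2FC distribution (absolute value — a
signed rule could never call down-regulation). Classes: both assays
significant and concordant → transcriptional; Ribo-Seq only →
translational; RNA-Seq only → buffering; both but opposite →
discordant; otherwise unchanged. The assignment is a pure function of the
two significance flags and signs, exhaustively tested on the 9-cell truth
table.

The secondary TE-change test fits, per gene, a negative-binomial GLM with
log link over both assays and conditions (`condition + assay +
condition:assay`, offsets = log TMM-effective library size) and reads the
interaction by likelihood ratio against chi-square(1). The gene-wise
Pearson method-of-moments dispersion from only n − p = 8 residual df is
noisy enough to make the plug-in LRT anticonservative (~0.10 at nominal
0.05), so dispersions are shrunk toward the experiment-wide median with a
prior weight of 20 residual-df, restoring calibration (~0.05–0.06) while
keeping ≥ 80% BH power on 4-fold planted TE effects at depth 5M.

## Class-wise correlation and the resampling null

Per regulatory class, Spearman's rho (average ranks on ties) over the
members' (CDS log2FC, upstream log2FC) pairs, where upstream is the 5'UTR
or uORF Ribo-Seq fold change. Significance against "any random gene set of
this size" uses B random subsets of the full pool without replacement;
`empirical_p = (1 + #{null ≤ observed}) / (B + 1)` for the one-sided
"more negative than chance" question (direction configurable). The +1
correction keeps p strictly positive; B = 1000 gives a floor of ~10⁻³.

## Synthetic data generator

Per gene: baseline abundance λ ~ log-normal(meanlog 3, sdlog 1); a
regulatory class drawn from configurable proportions (default 10% for each
of six regulated classes, 40% unchanged; a `paperlike` preset echoes the
observed 10–15% transcriptional / 6–12% translational split); an mRNA
multiplier a and a translation-efficiency multiplier b in stress, with
|log2 effect| = 2 exactly (transcriptional: a = ±4×; translational:
b = ±4×; buffering: a = ±4× with b compensating). Expected reads:

* RNA: λ·a split between UTR and CDS by length;
* Ribo CDS: λ·a·b·τ with the global arrest τ = 0.25 applied to every gene
  in stress (the uORF-independent mechanism);
* Ribo 5'UTR/uORF: λ·a·scanning·ρ with scanning = 0.1 (upstream density
  ~10% of CDS in normal conditions) and ρ = 1 for all genes except
  translationally up-regulated uORF genes, where ρ defaults to 0.3 and is
  anti-phased with the gene's realized CDS effect (b = 2 + δ, uORF change
  = log2 ρ − δ, δ ~ N(0, 0.35)) — the only class given per-gene effect
  spread, which is what makes the within-class anti-correlation
  detectable. A `uorf_dependent` switch instead couples uORF
  up-translation to proportional extra CDS repression, so the two
  mechanisms are distinguishable downstream.

Counts are negative binomial with gene-constant dispersion 0.1; per-sample
depth is 5e6 ± 15%. At read level (the `tiny` preset: 20 genes, 2
replicates, 2e4 reads/sample) genes are laid head-to-tail on both strands
with 100-nt spacers, 5'UTRs carry their planted uORF with an 18-nt
clearance from the UTR edges, and reads are emitted as ungapped SAM
records: P-sites land on a codon first base of the containing ORF with
probability 0.85 (else uniformly off-frame) and read start positions are
back-computed so the configured offset recovers the intended P-site; RNA
reads and non-uORF UTR footprints are uniform within their region. Reads
are emitted fully inside their source feature, so the per-(sample, gene,
region) emission ledger equals both overlap modes' counts exactly — an
invariant the tests assert. All randomness flows from one seed through
named SeedSequence spawn keys; fixtures are byte-identical across runs of
the same seed.

The larger presets (`calibration`, `paperlike`: 2000 genes, 3v3, depth 5e6)
are materialised at count level only — their contracts are count
statistics, and the read-level path is fully exercised at tiny scale.

What the generator does not emulate: sequencing errors, rRNA
contamination, splice-junction reads, elongation-inhibitor artefacts,
length-dependent capture biases, and within-class effect heterogeneity
outside the translational-up class. Passing tests therefore demonstrate
correctness of the machinery and calibration under NB noise, not
robustness to every artefact of real libraries.

## Problem sizes and runtimes

Unit and property tests run on the tiny read-level fixture and on
count-level simulations of 300–2000 genes; the statistical end-to-end
checks use the calibration preset (2000 genes, 12 samples, depth 5e6,
five seeds aggregated where a check is distributional). The full suite
completes in about a minute on one CPU; `scripts/acceptance.py` in well
under a minute.

## Known limitations

* Gene-level models only; isoform-resolved 5'UTRs and junction-aware
  P-site placement are out of scope.
* The translation score is deliberately not RibORF's SVM; absolute score
  values are comparable only within this pipeline.
* The TE interaction GLM is a secondary output; regulatory classes from
  the two-assay DGE carry the main conclusions (they resolve direction
  and assay of origin, which a TE test alone does not).
* Empirical p-values are bounded below by 1/(B+1); claims beyond that
  resolution require more draws.
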