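# riboshift

Analysis pipeline for the translational side of the stress response, built
around paired ribosome profiling (Ribo-Seq) and RNA-Seq data: when cells hit
stress, translation initiation on most coding sequences (CDS) is arrested,
while ribosome density in 5' untranslated regions (5'UTRs) — and in the
AUG-initiated upstream ORFs (uORFs) they contain — is largely insensitive.
`riboshift` quantifies that shift and asks where uORFs actively regulate
their downstream CDS.

Starting from a genome FASTA, a GFF3 annotation with CDS and 5'UTR features,
and aligned reads in SAM for ≥2 replicates × 2 conditions per assay, the
pipeline:

1. builds per-gene transcript models, merging multiple published 5'UTR
   annotation sources (longest UTR wins);
2. enumerates all AUG→STOP uORFs of ≥ 10 codons inside 5'UTRs;
3. counts reads per region with htseq-count semantics (`union` for CDS,
   `intersection_strict` for 5'UTRs) and places Ribo-Seq P-sites by
   read-length-specific offsets;
4. scores each uORF for active translation from 3-nt periodicity and
   coverage homogeneity: with f1 the in-frame P-site fraction and PME the
   relative entropy of in-frame coverage along the ORF,

   `score = sqrt( max(0, (f1 − 1/3) / (2/3)) × PME )  ∈ [0, 1]`,

   and calls uORFs with pooled reads ≥ 10 and score > 0.7 translated;
5. computes CPM fold changes, translational efficiency (TE = Ribo CPM / RNA
   CPM) and the per-gene and global 5'UTR(uORF):CDS density ratio shift
   between stress and normal;
6. runs differential expression per assay (depth-equalising subsampling →
   TMM normalisation → voom-style moderated t-test → BH), flags genes with
   adjusted p < 0.05 and |log2FC| above one SD of the assay's log2FC
   distribution, and classifies each gene as transcriptional (both assays,
   concordant), translational (Ribo-Seq only) or post-transcriptionally
   buffered (RNA-Seq only);
7. tests, per regulatory class, the Spearman correlation between upstream
   and CDS ribosome-density changes against an empirical null of B = 1000
   random same-size gene subsets.

A synthetic-data generator (`riboshift.synthetic_data`) plants all of this
structure — global CDS arrest, stress-insensitive uORF density,
regulatory classes, negative-binomial noise, 3-nt periodic footprints — and
emits either count tables or a full FASTA/GFF3/SAM experiment with an exact
per-read emission ledger, so every stage is verifiable without downloads.

## Worked example

The `analysis/` scripts run the whole pipeline on the synthetic experiment
(seed 7 by default) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_uorf_discovery.py
python analysis/03_density_shift.py
python analysis/04_differential_expression.py
python analysis/05_stress_correlation.py
```

`02_uorf_discovery.py` discovers 43 candidate uORFs across the 20-gene
read-level fixture and reports

```
16 uORFs called translated (pooled reads >= 10, score > 0.7); 12/12 planted uORFs recovered
```

— every planted periodic uORF scores above the 0.7 cutoff (mean score
0.873, mean in-frame fraction 0.851 against the planted 0.85).
`03_density_shift.py` measures the stress shift of upstream-to-CDS ribosome
density on the 2000-gene count-level experiment:

```
global 5'UTR:CDS density shift (stress/normal): 3.92-fold
per-gene shifts: 1999 genes pass the 10-read filter, 87.8% shifted up
```

recovering the planted 4-fold CDS arrest (τ = 0.25).
`04_differential_expression.py` reports per-class recovery of the planted
regulation (recall 0.87–0.98, cross-class confusion ≤ 0.094), and
`05_stress_correlation.py` finds

```
translational_up uORF genes (n=100): rho -0.395, probability by chance 0.000999
```

— uORF density changes anti-correlate with CDS changes exactly in the class
of translationally up-regulated genes, while the full gene pool correlates
positively (rho +0.27), the signature of uORFs acting as stress switches.

## Layout

- `src/riboshift/` — the library: `annotation_io`, `uorf_discovery`,
  `read_counting`, `translation_scoring`, `quantification`,
  `differential_expression`, `stress_analysis`, `synthetic_data`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end statistical tests.
- `docs/methods.md` — models, parameters, numerical choices, limitations.
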