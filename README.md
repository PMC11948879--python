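# methcohort

Cohort-scale visualization of nucleotide-modification frequencies.

Long-read sequencers call base modifications (5mC, 5hmC) per read, and
phasing assigns each read to one of its two haplotypes — which makes
allele-specific methylation (imprinting, X-inactivation, ASM candidates)
directly visible. But most methylation browsers draw one or a handful of
samples; a population-scale cohort means *hundreds* of columns (two
haplotypes per individual). methcohort is built for that shape:

* **Frequency tables.** The central object is a modification frequency
  table: one row per genomic position, one column per individual or
  haplotype, cells = fraction of reads called modified,
  `f(s, j) = n_modified / n_valid ∈ [0, 1]`, with explicit missingness.
  Tables are written as bgzipped TSV with a tabix index, so a region of an
  epigenome-wide, 450-column table is fetched in milliseconds.
* **Inputs.** BAM/CRAM with MM/ML modified-base tags (haplotype-split on
  the HP tag, CpG-restricted against a reference, both strands combined
  onto the forward C), nanopolish methylation-caller TSVs (log-likelihood
  ratio threshold |LLR| ≥ 2, call groups split into member CpGs), or any
  precomputed frequency TSV.
* **Heatmaps.** A region renders as a self-contained HTML heatmap —
  positions top to bottom, samples left to right, purple (0) → yellow (1),
  missing cells gray — with an optional GFF3 gene/exon track at the left
  and an optional sample dendrogram above.
* **Clustering with a missing-data protocol.** Columns with ≥ 40% missing
  cells are removed; remaining gaps are filled by linear interpolation in
  genomic position (methylation is locally coregulated, so closer
  positions get more weight); columns with uninterpolatable edge gaps are
  dropped; the rest are clustered (complete linkage, Euclidean distance)
  and the heatmap shows the imputed matrix in dendrogram leaf order.
* **A cohort pipeline.** Per-sample haplotype counts → fixed 25-Mb genomic
  chunks (bounded memory, resumable) → merged, sorted, indexed cohort
  table.

## Worked example

Simulate a 3-individual imprinted locus (one haplotype highly methylated,
the other lowly) and run the two CLI workflows:

```python
from methcohort.simulate import CohortSpec, make_reference, simulate_modbam

spec = CohortSpec(n_individuals=3, n_sites=8, depth=10, seed=4)
reference = make_reference(n_cpg=8, spacing=10, seed=4)
bams, fasta, truth = simulate_modbam(spec, reference, ".")
```

```sh
$ methcohort table IND1.bam IND2.bam IND3.bam --reference ref.fa \
      --partition -o cohort.tsv.gz
INFO methcohort subcommand=table inputs=3 sites=8 columns=6 missing_pct=0.0 output=cohort.tsv.gz

$ methcohort plot --table cohort.tsv.gz --region "chrS:1-100" \
      --cluster -o region.html
INFO methcohort subcommand=plot region=chrS:1-100 sites=8 columns=6 output=region.html
```

The table has one `_H1` and one `_H2` column per BAM (6 columns from 3
files) and reads back as:

```
chrom	position	IND1_H1	IND1_H2	IND2_H1	IND2_H2	IND3_H1	IND3_H2
chrS	1	0.8000	0.1000	0.8000	0.0000	0.8000	0.1000
chrS	11	0.9000	0.1000	0.7000	0.2000	1.0000	0.1000
chrS	21	0.4000	0.1000	0.9000	0.0000	0.7000	0.2000
```

Each cell is an exact read-count ratio: at position 1, 8 of IND1's 10
H1-tagged reads were called modified (0.8000) versus 1 of 10 on H2 — the
alternating high/low column pattern is the imprinting signature the
heatmap makes visible at a glance. `region.html` contains the clustered
heatmap (H1 columns group together on one side of the dendrogram's root,
H2 on the other) and embeds the displayed matrix as JSON, retrievable
with `methcohort.extract_payload("region.html")`.

Region strings accept publication formatting, e.g.
`chr20:58,839,718-58,911,192` (the GNAS imprinted locus).

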