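# Methods

## The frequency-table model

The canonical object is a matrix F with rows indexed by (chromosome,
1-based position) and columns by sample or haplotype; F[s, j] is the
fraction of valid reads at site s called modified in column j, carried
with the integer counts it came from (n_modified / n_valid). A site with
n_valid = 0 is *missing* for that column, not zero: absence of evidence is
kept distinct from absence of methylation throughout.

Coordinates are 1-based and inclusive everywhere a user sees them (region
strings, the position column, hover text); half-open arithmetic appears
only at htslib call sites. Rows are sorted by natural chromosome order
(chr2 < chr10) then position; duplicate (chrom, position) rows are an
error, because in a cohort pipeline they indicate double-counted chunks,
not a merge opportunity. Frequencies are serialized with 4 decimals —
sub-read-count precision carries no information and the files are written
at epigenome × cohort scale. Missing cells serialize as empty fields; the
reader also accepts "NA" and "nan". On-disk tables are bgzip-compressed
with a tabix index (sequence = column 1, begin = end = column 2, one
header line skipped), which makes region retrieval O(log n + output).

## MM/ML decoding

The SAM MM tag stores, per canonical base and modification code,
skip-counts over occurrences of that base *in sequenced orientation*; ML
stores matching 8-bit probabilities (per listed position, codes in listed
order). The decoder walks occurrences with the skip-counts, maps each
listed base through the alignment to a 1-based reference coordinate
(soft-clipped and inserted bases drop out), and flips indices for
reverse-strand alignments so the caller's C lands on the reference G of
the CpG. Conventions:

* Dequantization uses interval midpoints, p = (q + 0.5)/256. Any point in
  [q/256, (q+1)/256) is defensible; the midpoint is the symmetric choice
  and keeps p strictly inside (0, 1) for explicit calls.
* A run flagged `.` implies every unlisted canonical base is unmodified;
  those are materialized as probability-0 calls so they count toward
  coverage. A `?` run (and a missing flag is treated as the historical
  `.`) says nothing about unlisted bases.
* Runs with `-` strand (modification on the strand opposite the sequenced
  base) are rejected with a clear error; CpG callers emit `+` runs only.
* Only primary alignments with MAPQ ≥ 1 contribute; secondary,
  supplementary and duplicate records are skipped.

Aggregation restricts calls to CpG sites taken from the reference (the C
of each CG dinucleotide), combines strands by shifting reverse-strand
G-calls one base left onto the paired forward C, and counts a call as
modified when p ≥ 0.5 (boundary inclusive). An optional confidence band
(`min_confidence`, default 0) drops calls with max(p, 1−p) below it;
adaptive percentile filtering as done by pileup tools is deliberately out
of scope — a fixed, documented rule is reproducible. Per-strand output is
not offered; combining is the decision that makes haplotype columns dense
enough to cluster, and it is flagged here because other pipelines differ.

Haplotype partitioning groups reads by the integer HP tag into H1/H2;
untagged reads are excluded from haplotype columns by default (an
`include_ungrouped` option adds a third column per sample). Multithreading
parallelizes over (file, contig) pairs and reassembles results in a fixed
order, so the output is bit-identical for any thread count.

## Nanopolish conversion

The caller reports one row per (read, CpG group) with a log-likelihood
ratio; |LLR| < 2.0 rows are discarded (the caller's canonical frequency
helper's threshold; configurable), and a group with k motifs splits into k
per-CpG calls at the CG offsets of its sequence context — member k sits at
start + (offset_k − offset_0), each member inheriting the group call
(methylated iff LLR > 0). The caller's 0-based coordinates are converted
to 1-based at parse time. Motif positions are already forward-strand
anchored for both sequencing strands, so no further strand combining is
applied.

## Missing-data protocol and clustering

Order is fixed: (1) remove columns with missing fraction ≥ 0.40 — the
boundary is inclusive ("40% or more"); (2) interpolate remaining gaps
linearly *in genomic position* within each column and chromosome
(position-weighted, not row-rank-weighted: a gap 1/3 of the genomic way
between its neighbors takes 1/3 of the value step); (3) remove columns
with gaps left after interpolation — exactly the leading/trailing gaps,
since edges have one neighbor and extrapolation is refused; (4) cluster
columns by complete-linkage agglomeration on Euclidean distances.
Frequencies already share the [0, 1] scale, so no standardization is
applied. Interpolation is idempotent, never touches observed cells, and
imputed values are bounded by their neighbors.

Dendrogram leaf order is made deterministic by a fixed convention: at
every merge, the subtree containing the lexicographically smallest
original column label is drawn on the left. Dendrogram libraries disagree
on this tie-break, and heatmap column order must be reproducible. The
heatmap displays the imputed matrix when clustering is on.

## Annotation track and figure

GFF3 genes overlapping the query region are kept with their full
transcript/exon hierarchy (ID/Parent-resolved; any feature type whose
parent is a gene counts as a transcript, which absorbs the
GENCODE/Ensembl dialect difference); exons with unresolvable parents are
dropped with a logged count. Display rows come from greedy interval
coloring over genes sorted by (start, id): deterministic, collision-free,
compact.

The figure is written as self-contained HTML: an SVG heatmap (positions
vertical, samples horizontal, gene track left, dendrogram above) plus the
full displayed matrix embedded as a JSON payload. The color ramp is
viridis with the domain pinned to [0, 1] — endpoint colors, purple for
unmethylated and yellow for methylated, never rescale to the data —
and missing cells render light gray, outside the ramp. Hover text on each
cell carries chrom:position (1-based), sample and frequency. Rendering is
a pure function of the figure document, so identical inputs give
byte-identical files. The payload is what tests compare cellwise against
the input matrix: nothing is binned or resampled at these sizes.

## Cohort pipeline

Per sample: haplotype-partitioned counts over all contigs, split into
fixed 25,000,000-bp windows (window k covers [k·25 Mb + 1, (k+1)·25 Mb],
so no chunk spans ≥ 25 Mb) and written as per-chunk tables; a per-sample
done-marker makes reruns skip completed work, so an interrupted run
resumes to an identical final table. Chunks are then merged — column
collisions are legal only across disjoint position ranges; conflicting
non-missing duplicates abort with the offending cell — sorted, written
and indexed. Manifest entries pointing at missing files go to a failure
report while other samples proceed; the exit status is nonzero when any
entry failed.

## Synthetic data

The generator produces every input format with exact bookkeeping, so
downstream assertions are integer-ratio identities rather than
statistical checks. `make_reference` plants CG dinucleotides at fixed
spacing (positions depend only on count and spacing, never the seed) and
forbids stray CGs elsewhere. `simulate_modbam` emits pre-aligned reads —
constructed CIGARs, no aligner — covering the whole reference, HP-tagged
1/2, with per-(read, CpG) Bernoulli draws at the haplotype's methylation
rate encoded as ML scores 230 (p ≈ 0.90) or 10 (p ≈ 0.04); forward and
reverse reads, soft clips, insertions and both MM flag dialects are
injected round-robin to stress the decoder. `simulate_cohort_table` draws
per-site rates Beta(μ·c, (1−μ)·c) with c = 30 around haplotype means
(defaults 0.85 for H1, 0.10 for H2 — an imprinted block), binomial
sampling at depth 20, and per-column missingness masks.

Default desk-scale shape: 20 individuals × 2 haplotypes × 200 CpGs ×
depth 20, which runs in seconds; the 452-column consortium shape is
exercised at depth 1 for the column-count check only. What the generator
does *not* emulate: basecalling error profiles, coverage heterogeneity
along the genome, phasing switch errors, or non-CpG modification contexts.
Passing tests therefore demonstrate the correctness of decoding,
counting, indexing, imputation and clustering mechanics — not robustness
to real-data noise in modification calls themselves.

## Numerical and degenerate-input choices

* Modified-call boundary p = 0.5 counts as modified; missingness boundary
  40% counts as removed; nanopolish |LLR| = cutoff counts as retained.
* Empty tables round-trip (header-only file with a valid index); a region
  query on an absent chromosome returns an empty table with the header's
  columns; clustering with < 2 surviving columns, or a figure from an
  empty table, is an explicit error rather than a degenerate output.
* The bare-chromosome region uses 2³¹ − 1 as its "to end" sentinel — the
  htslib coordinate ceiling.
* Merge treats *equal* duplicated cells as benign (chunk-boundary
  overlap) and only conflicting values as errors.

## Known limitations

Single-code columns only (5mC or 5hmC per run, no combined-code mode);
no bedMethyl output; no per-strand (uncombined) tables; no GTF input;
no adaptive call filtering; the HTML figure is static markup — it has
native browser hover but no pan/zoom scripting.
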