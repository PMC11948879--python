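"""Synthetic inputs with exact ground truth, for testing and demos.

Every generator is seed-deterministic and keeps integer-count bookkeeping,
so downstream frequency assertions are exact ratios, never statistical.
Reads are emitted pre-aligned (constructed CIGARs), with reverse-strand
reads, soft clips, insertions and both MM flag dialects ('.' and '?')
injected deliberately to stress the decoder. There is no error model: the
truth is the counts, not realistic reads.

The default cohort shape (20 individuals x 2 haplotypes x 200 CpGs x
depth 20) emulates an imprinted locus — one haplotype highly methylated,
the other lowly — at a scale that runs in seconds.
"""

from __future__ import annotations

import os
from array import array
from dataclasses import dataclass, field

import numpy as np
import pysam

from .tables import FrequencyTable
from .regions import GenomicRegion

#: 8-bit scores used for simulated calls: dequantize to ~0.9004 and ~0.0410.
Q_MOD = 230
Q_UNMOD = 10

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CohortSpec:
    """Shape and signal of a simulated imprinted cohort."""

    n_individuals: int = 20
    n_sites: int = 200
    spacing: int = 10
    h1_mean: float = 0.85
    h2_mean: float = 0.10
    concentration: float = 30.0  # Beta concentration of per-site rates
    depth: int = 20
    missing_rate: float = 0.0
    chrom: str = "chrS"
    seed: int = 0

    def sample_names(self) -> list[str]:
        width = len(str(self.n_individuals))
        return [f"IND{i + 1:0{width}d}" for i in range(self.n_individuals)]


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


def make_reference(
    n_cpg: int, spacing: int = 10, seed: int = 0
) -> tuple[str, list[int]]:
    """Random sequence whose CG dinucleotides sit exactly at fixed positions.

    CpG k occupies 1-based positions (k*spacing + 1, k*spacing + 2); filler
    bases are random but never allowed to create an extra CG, so the CpG
    coordinates depend only on ``n_cpg`` and ``spacing``, not the seed.
    """
    if n_cpg < 1 or spacing < 2:
        raise ValueError("need n_cpg >= 1 and spacing >= 2")
    rng = np.random.default_rng(seed)
    positions = [k * spacing + 1 for k in range(n_cpg)]
    length = positions[-1] + spacing  # tail padding after the last CpG
    planted = {}
    for p in positions:
        planted[p - 1] = "C"
        planted[p] = "G"
    bases = []
    alphabet = "ACGT"
    for i in range(length):
        if i in planted:
            bases.append(planted[i])
            continue
        b = alphabet[rng.integers(4)]
        if b == "G" and bases and bases[-1] == "C":
            b = "A"  # would create a stray CpG
        if b == "C" and i + 1 in planted and planted[i + 1] == "C":
            pass  # CC is harmless
        bases.append(b)
    return "".join(bases), positions


def write_fasta(seq: str, chrom: str, path: str | os.PathLike) -> str:
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)
    return path


# ---------------------------------------------------------------------------
# MM/ML encoding (the inverse of the decoder, used only to build fixtures)
# ---------------------------------------------------------------------------


def encode_mm_ml(
    seq: str,
    calls: dict[int, int],
    flag: str = "?",
    base: str = "C",
    code: str = "m",
) -> tuple[str, list[int]]:
    """Encode per-base calls into an MM string and ML byte list.

    ``calls`` maps 0-based indexes into ``seq`` (sequenced orientation,
    each must hold ``base``) to 8-bit scores. With flag '.', unmodified
    calls (score < 128) may be omitted from the listing — they are implied
    — so only scores >= 128 are listed; with '?', every call is listed.
    """
    occurrences = [i for i, b in enumerate(seq) if b == base]
    occ_rank = {i: r for r, i in enumerate(occurrences)}
    if flag == ".":
        listed = sorted(i for i, q in calls.items() if q >= 128)
    else:
        listed = sorted(calls)
    deltas = []
    prev_rank = -1
    for i in listed:
        rank = occ_rank[i]
        deltas.append(rank - prev_rank - 1)
        prev_rank = rank
    mm = f"{base}+{code}{flag}" + "".join(f",{d}" for d in deltas) + ";"
    ml = [calls[i] for i in listed]
    return mm, ml


# ---------------------------------------------------------------------------
# modBAM simulation
# ---------------------------------------------------------------------------


@dataclass
class ModBamTruth:
    """Exact per-column, per-site counts behind a simulated file set."""

    counts: dict[str, dict[int, list[int]]] = field(default_factory=dict)

    def add(self, column: str, position: int, modified: bool) -> None:
        cell = self.counts.setdefault(column, {}).setdefault(position, [0, 0])
        cell[1] += 1
        if modified:
            cell[0] += 1

    def frequency(self, column: str, position: int) -> float:
        n_mod, n_valid = self.counts[column][position]
        return n_mod / n_valid

    def to_table(self, chrom: str) -> FrequencyTable:
        columns = sorted(self.counts)
        positions = sorted({p for c in columns for p in self.counts[c]})
        values = np.full((len(positions), len(columns)), np.nan)
        for j, c in enumerate(columns):
            for i, p in enumerate(positions):
                if p in self.counts[c]:
                    values[i, j] = self.frequency(c, p)
        sites = [(chrom, p) for p in positions]
        return FrequencyTable.from_records(sites, columns, values)


def _make_read(
    name: str,
    ref_seq: str,
    chrom_id: int,
    is_reverse: bool,
    style: str,
    cpg_scores: dict[int, int],
    hp: int | None,
    rng: np.random.Generator,
) -> pysam.AlignedSegment:
    """Build one aligned read covering the whole reference.

    ``cpg_scores`` maps 1-based CpG C positions to 8-bit scores.
    ``style`` is one of "plain", "softclip", "insert" and controls the
    CIGAR decorations used to stress the decoder.
    """
    length = len(ref_seq)
    sam_seq = ref_seq
    cigar = [(0, length)]  # M
    # Map 0-based reference offset -> 0-based SAM read index.
    ref_to_sam = {i: i for i in range(length)}
    if style == "softclip":
        clip = "".join("ACTGC"[rng.integers(5)] for _ in range(6))
        sam_seq = clip + sam_seq
        cigar = [(4, 6), (0, length)]
        ref_to_sam = {i: i + 6 for i in range(length)}
    elif style == "insert":
        mid = length // 2
        ins = "".join("CCTAG"[rng.integers(5)] for _ in range(5))
        sam_seq = sam_seq[:mid] + ins + sam_seq[mid:]
        cigar = [(0, mid), (1, 5), (0, length - mid)]
        ref_to_sam = {
            i: (i if i < mid else i + 5) for i in range(length)
        }

    # Scores keyed by SAM index of the called base: the C itself on the
    # forward strand, the sequenced-C over the reference G on the reverse.
    sam_scores: dict[int, int] = {}
    for pos, q in cpg_scores.items():
        ref_off = (pos - 1) if not is_reverse else pos  # C or paired G
        sam_scores[ref_to_sam[ref_off]] = q

    sam_len = len(sam_seq)
    if is_reverse:
        seq_sequenced = revcomp(sam_seq)
        seq_scores = {sam_len - 1 - j: q for j, q in sam_scores.items()}
    else:
        seq_sequenced = sam_seq
        seq_scores = dict(sam_scores)
    flag_char = "." if style == "plain" and not is_reverse else "?"
    mm, ml = encode_mm_ml(seq_sequenced, seq_scores, flag=flag_char)

    read = pysam.AlignedSegment()
    read.query_name = name
    read.query_sequence = sam_seq
    read.flag = 16 if is_reverse else 0
    read.reference_id = chrom_id
    read.reference_start = 0
    read.mapping_quality = 60
    read.cigartuples = cigar
    read.query_qualities = pysam.qualitystring_to_array("I" * len(sam_seq))
    read.set_tag("MM", mm)
    read.set_tag("ML", array("B", ml))
    if hp is not None:
        read.set_tag("HP", hp)
    return read


def simulate_modbam(
    spec: CohortSpec,
    reference: tuple[str, list[int]],
    out_dir: str | os.PathLike,
) -> tuple[list[str], str, ModBamTruth]:
    """Write one modBAM per individual plus the reference FASTA.

    Each individual gets ``depth`` reads per haplotype, HP-tagged 1/2,
    spanning the whole reference. Per read and CpG a Bernoulli draw at the
    haplotype's methylation rate becomes score 230 (modified) or 10
    (unmodified). Returns (bam paths, fasta path, truth counts keyed by
    ``<sample>_H<hap>`` columns).
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    seq, positions = reference
    fasta = write_fasta(seq, spec.chrom, os.path.join(out_dir, "ref.fa"))
    rng = np.random.default_rng(spec.seed)
    truth = ModBamTruth()
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": len(seq)}],
    }
    styles = ["plain", "softclip", "insert"]
    bam_paths = []
    for sample in spec.sample_names():
        path = os.path.join(out_dir, f"{sample}.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for hap, rate in ((1, spec.h1_mean), (2, spec.h2_mean)):
                for d in range(spec.depth):
                    is_reverse = d % 2 == 1
                    style = styles[d % 3]
                    scores = {}
                    for pos in positions:
                        modified = bool(rng.random() < rate)
                        scores[pos] = Q_MOD if modified else Q_UNMOD
                        truth.add(f"{sample}_H{hap}", pos, modified)
                    read = _make_read(
                        f"{sample}_h{hap}_r{d}",
                        seq,
                        0,
                        is_reverse,
                        style,
                        scores,
                        hp=hap,
                        rng=rng,
                    )
                    bam.write(read)
        pysam.index(path)
        bam_paths.append(path)
    return bam_paths, fasta, truth


# ---------------------------------------------------------------------------
# Cohort frequency tables
# ---------------------------------------------------------------------------


def simulate_cohort_table(
    spec: CohortSpec,
) -> tuple[FrequencyTable, dict[str, str]]:
    """Desk-scale analogue of a consortium-wide haplotype table.

    Two columns per individual (``<ID>_H1`` high-methylated, ``<ID>_H2``
    low), per-site rates Beta-distributed around the haplotype mean,
    frequencies binomial at ``depth`` reads, missing cells masked at
    ``missing_rate`` per column. Returns the table and column -> H1/H2
    truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    positions = [k * spec.spacing + 1 for k in range(spec.n_sites)]
    columns: list[str] = []
    labels: dict[str, str] = {}
    mat = []
    for sample in spec.sample_names():
        for hap, mean in ((1, spec.h1_mean), (2, spec.h2_mean)):
            name = f"{sample}_H{hap}"
            a = mean * spec.concentration
            b = (1 - mean) * spec.concentration
            rates = rng.beta(a, b, size=spec.n_sites)
            if spec.depth > 0:
                freqs = rng.binomial(spec.depth, rates) / spec.depth
            else:
                freqs = rates
            if spec.missing_rate > 0:
                mask = rng.random(spec.n_sites) < spec.missing_rate
                freqs = np.where(mask, np.nan, freqs)
            columns.append(name)
            labels[name] = f"H{hap}"
            mat.append(freqs)
    sites = [(spec.chrom, p) for p in positions]
    table = FrequencyTable.from_records(sites, columns, np.array(mat).T)
    return table, labels


# ---------------------------------------------------------------------------
# GFF3 and nanopolish fixtures
# ---------------------------------------------------------------------------


@dataclass
class GeneSpec:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    #: list of (transcript_id, start, end, [(exon_start, exon_end), ...])
    transcripts: list = field(default_factory=list)


def make_gff3(genes: list[GeneSpec], path: str | os.PathLike) -> str:
    """Write a GENCODE-dialect GFF3 (bgzipped when path ends in .gz)."""
    path = os.fspath(path)
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.name}"
        )
        for tid, t_start, t_end, exons in g.transcripts:
            lines.append(
                f"{g.chrom}\tsim\ttranscript\t{t_start}\t{t_end}\t.\t"
                f"{g.strand}\t.\tID={tid};Parent={g.gene_id}"
            )
            for k, (e_start, e_end) in enumerate(exons, 1):
                lines.append(
                    f"{g.chrom}\tsim\texon\t{e_start}\t{e_end}\t.\t"
                    f"{g.strand}\t.\tID={tid}.exon{k};Parent={tid}"
                )
    text = "\n".join(lines) + "\n"
    if path.endswith((".gz", ".bgz")):
        import tempfile

        fd, tmp = tempfile.mkstemp(suffix=".gff3")
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        pysam.tabix_compress(tmp, path, force=True)
        os.unlink(tmp)
    else:
        with open(path, "w") as fh:
            fh.write(text)
    return path


NANOPOLISH_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
)


def write_nanopolish(records, path: str | os.PathLike) -> str:
    """Write records in the caller's dialect (0-based start/end)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write("\t".join(NANOPOLISH_COLUMNS) + "\n")
        for r in records:
            llr = r.log_lik_ratio
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        r.strand,
                        str(r.start - 1),
                        str(r.end - 1),
                        r.read_name,
                        f"{llr:.2f}",
                        f"{llr / 2:.2f}",
                        f"{-llr / 2:.2f}",
                        "1",
                        str(r.num_motifs),
                        r.sequence,
                    ]
                )
                + "\n"
            )
    return path


def simulate_nanopolish(
    positions: list[int],
    chrom: str = "chrS",
    depth: int = 10,
    meth_prob: float = 0.7,
    seed: int = 0,
):
    """Single-motif call records with exact per-site truth counts.

    LLR magnitude is 8 (always retained at the default cutoff); sign
    follows a Bernoulli(meth_prob) draw. Returns (records, truth) with
    truth[pos] = [n_methylated, n_valid].
    """
    from .nanopolish import NanopolishRecord

    rng = np.random.default_rng(seed)
    records = []
    truth: dict[int, list[int]] = {p: [0, 0] for p in positions}
    for pos in positions:
        for d in range(depth):
            methylated = bool(rng.random() < meth_prob)
            llr = 8.0 if methylated else -8.0
            truth[pos][1] += 1
            if methylated:
                truth[pos][0] += 1
            records.append(
                NanopolishRecord(
                    chrom=chrom,
                    strand="+",
                    start=pos,
                    end=pos,
                    read_name=f"np_{pos}_{d}",
                    log_lik_ratio=llr,
                    num_motifs=1,
                    sequence="AATCGTA",
                )
            )
    return records, truth
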