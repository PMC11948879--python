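"""Decode MM/ML modified-base tags and aggregate CpG methylation.

Basecallers emit per-read modification calls in two SAM optional tags: MM
lists, per canonical base and modification code, skip-counts over
occurrences of that base in the *sequenced* read orientation; ML carries
the matching 8-bit quantized probabilities. This module decodes those tags
onto reference coordinates, partitions reads by their haplotype (HP) tag,
and counts per-CpG modified/valid calls with reverse-strand calls folded
onto the forward-strand C (strand combining).

Conventions (documented because every one of them is an off-by-one trap):

* An 8-bit score q dequantizes to the interval midpoint (q + 0.5) / 256.
* A call with probability >= 0.5 counts as modified; ``min_confidence``
  (default 0: keep everything) drops calls with max(p, 1-p) below it.
* MM runs flagged '.' imply that unlisted canonical bases are unmodified:
  they are emitted as probability-0 calls and count toward coverage. Runs
  flagged '?' (or the modern default) say nothing about unlisted bases.
* Only primary alignments with mapping quality >= 1 contribute; secondary,
  supplementary and duplicate reads are skipped.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .errors import DataError, MalformedTagError, NoModificationTagsError
from .regions import GenomicRegion
from .tables import FrequencyTable, SiteCount, counts_to_table

_CANONICAL = set("ACGTUN")


@dataclass(frozen=True)
class BaseModCall:
    """One per-read, per-base modification probability on the reference."""

    read_id: str
    chrom: str
    ref_position: int  # 1-based coordinate of the called base
    strand_of_call: str  # '+' or '-': the read's alignment strand
    mod_code: str  # e.g. 'm' (5mC), 'h' (5hmC)
    probability: float


def dequantize(q: int) -> float:
    """Map an 8-bit ML score to the midpoint of its probability interval."""
    if not 0 <= q <= 255:
        raise MalformedTagError(f"ML value {q} outside 0..255")
    return (q + 0.5) / 256.0


def _parse_mm_runs(mm: str, read_id: str):
    """Yield (base, strand, codes, flag, deltas) per semicolon run."""
    for run in mm.rstrip(";").split(";"):
        if not run:
            continue
        head, _, tail = run.partition(",")
        deltas = [] if not tail else tail.split(",")
        if len(head) < 3:
            raise MalformedTagError(f"{read_id}: malformed MM run {run!r}")
        base, strand = head[0].upper(), head[1]
        rest = head[2:]
        flag = "?" if rest.endswith("?") else "."
        codes = rest.rstrip(".?")
        if base not in _CANONICAL:
            raise MalformedTagError(
                f"{read_id}: unknown canonical base {base!r} in MM tag"
            )
        if strand not in "+-":
            raise MalformedTagError(
                f"{read_id}: bad strand {strand!r} in MM run {run!r}"
            )
        if not codes:
            raise MalformedTagError(f"{read_id}: MM run {run!r} lists no code")
        parsed = []
        for d in deltas:
            try:
                v = int(d)
            except ValueError:
                raise MalformedTagError(
                    f"{read_id}: non-integer MM delta {d!r}"
                ) from None
            if v < 0:
                raise MalformedTagError(f"{read_id}: negative MM delta {v}")
            parsed.append(v)
        yield base, strand, codes, flag, parsed


def decode_read_mods(
    seq: str,
    is_reverse: bool,
    aligned_pairs: Mapping[int, int],
    mm: str,
    ml: Sequence[int],
    *,
    read_id: str = "read",
    chrom: str = "chrom",
) -> list[BaseModCall]:
    """Decode one read's MM/ML tags into reference-anchored calls.

    Parameters
    ----------
    seq:
        Read bases in the orientation they were sequenced (for a
        reverse-strand alignment this is the reverse complement of the SAM
        SEQ field).
    aligned_pairs:
        0-based SAM read index -> 1-based reference position, for aligned
        bases only; soft-clipped/inserted bases are absent and their calls
        are dropped.
    """
    seq = seq.upper()
    length = len(seq)
    calls: list[BaseModCall] = []
    ml_cursor = 0
    strand_of_call = "-" if is_reverse else "+"

    def emit(seq_index: int, code: str, prob: float) -> None:
        sam_index = length - 1 - seq_index if is_reverse else seq_index
        ref = aligned_pairs.get(sam_index)
        if ref is None:
            return
        calls.append(
            BaseModCall(read_id, chrom, ref, strand_of_call, code, prob)
        )

    for base, strand, codes, flag, deltas in _parse_mm_runs(mm, read_id):
        if strand != "+":
            raise MalformedTagError(
                f"{read_id}: MM '-' strand runs are not supported "
                "(CpG callers emit '+' runs)"
            )
        if base == "N":
            occurrences = np.arange(length)
        else:
            occurrences = np.flatnonzero(
                np.frombuffer(seq.encode(), np.uint8) == ord(base)
            )
        listed: set[int] = set()
        cursor = -1
        for delta in deltas:
            cursor += delta + 1
            if cursor >= len(occurrences):
                raise MalformedTagError(
                    f"{read_id}: MM deltas overrun the read's "
                    f"{len(occurrences)} {base!r} bases"
                )
            seq_index = int(occurrences[cursor])
            listed.add(seq_index)
            for code in codes:
                if ml_cursor >= len(ml):
                    raise MalformedTagError(
                        f"{read_id}: ML shorter than MM calls"
                    )
                emit(seq_index, code, dequantize(int(ml[ml_cursor])))
                ml_cursor += 1
        if flag == ".":
            # Implicit-unmodified: every unlisted canonical base is an
            # explicit probability-0 call for each code in this run.
            for seq_index in occurrences:
                if int(seq_index) not in listed:
                    for code in codes:
                        emit(int(seq_index), code, 0.0)
    if ml_cursor != len(ml):
        raise MalformedTagError(
            f"{read_id}: ML has {len(ml)} values but MM encodes {ml_cursor}"
        )
    return calls


def partition_reads(
    reads: Iterable,
    tag_name: str = "HP",
    prefix: str = "H",
) -> dict[str, list]:
    """Group reads by an integer haplotype tag.

    Reads carrying tag value v go under ``prefix + str(v)`` (HP=1 -> "H1");
    reads without the tag go under ``"ungrouped"``. The groups are a
    disjoint cover of the input.
    """
    groups: dict[str, list] = {}
    for read in reads:
        if read.has_tag(tag_name):
            label = f"{prefix}{read.get_tag(tag_name)}"
        else:
            label = "ungrouped"
        groups.setdefault(label, []).append(read)
    return groups


def cpg_sites(reference_seq: str) -> list[int]:
    """1-based positions of the C of every CG dinucleotide (forward strand)."""
    arr = np.frombuffer(reference_seq.upper().encode(), np.uint8)
    if arr.size < 2:
        return []
    hits = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    return [int(i) + 1 for i in hits]


def aggregate_cpg(
    calls: Iterable[BaseModCall],
    sites: Sequence[int],
    mod_code: str = "m",
    mod_threshold: float = 0.5,
    min_confidence: float = 0.0,
    *,
    sample: str = "sample",
    chrom: str | None = None,
) -> list[SiteCount]:
    """Count modified/valid calls per CpG site for one sample group.

    Reverse-strand calls land on the G of a CpG; they are shifted one base
    left onto the paired forward-strand C so both strands pool into a
    single per-CpG frequency. Calls at non-CpG positions are ignored.
    """
    siteset = set(sites)
    counters: dict[tuple[str, int], list[int]] = {}
    for call in calls:
        if call.mod_code != mod_code:
            continue
        pos = call.ref_position
        if call.strand_of_call == "-":
            pos -= 1  # G of the CpG -> paired forward C
        if pos not in siteset:
            continue
        p = call.probability
        if max(p, 1.0 - p) < min_confidence:
            continue
        key = (chrom or call.chrom, pos)
        c = counters.setdefault(key, [0, 0])
        c[1] += 1
        if p >= mod_threshold:
            c[0] += 1
    return [
        SiteCount(ch, pos, sample, n_mod, n_valid)
        for (ch, pos), (n_mod, n_valid) in sorted(counters.items())
    ]


# ---------------------------------------------------------------------------
# Whole-file aggregation
# ---------------------------------------------------------------------------


def _read_aligned_pairs(read: pysam.AlignedSegment) -> dict[int, int]:
    """SAM read index (0-based) -> 1-based reference position."""
    return {
        q: r + 1
        for q, r in read.get_aligned_pairs(matches_only=True)
    }


def _usable(read: pysam.AlignedSegment) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < 1
    )


def _mod_tags(read: pysam.AlignedSegment) -> tuple[str, Sequence[int]] | None:
    mm = ml = None
    for name in ("MM", "Mm"):
        if read.has_tag(name):
            mm = read.get_tag(name)
            break
    for name in ("ML", "Ml"):
        if read.has_tag(name):
            ml = read.get_tag(name)
            break
    if mm is None:
        return None
    return mm, list(ml) if ml is not None else []


def decode_alignment(read: pysam.AlignedSegment, chrom: str) -> list[BaseModCall] | None:
    """Decode one pysam alignment; None when it carries no MM tag."""
    tags = _mod_tags(read)
    if tags is None:
        return None
    mm, ml = tags
    seq = read.get_forward_sequence()
    if seq is None:
        raise MalformedTagError(f"{read.query_name}: no sequence stored")
    return decode_read_mods(
        seq,
        read.is_reverse,
        _read_aligned_pairs(read),
        mm,
        ml,
        read_id=read.query_name,
        chrom=chrom,
    )


def _process_contig(
    path: str,
    contig: str,
    reference: str,
    sample: str,
    region: GenomicRegion | None,
    partition: bool,
    tag_name: str,
    prefix: str,
    mod_code: str,
    mod_threshold: float,
    min_confidence: float,
    include_ungrouped: bool,
) -> tuple[list[SiteCount], int, int]:
    """Aggregate one (file, contig) pair. Returns (counts, n_reads, n_tagged)."""
    with pysam.FastaFile(reference) as fa:
        if contig not in fa.references:
            return [], 0, 0
        sites = cpg_sites(fa.fetch(contig))
    if region is not None:
        # Fetched reads overhang the region; keep only sites inside it.
        sites = [p for p in sites if region.start <= p <= region.end]
    counts: list[SiteCount] = []
    n_reads = n_tagged = 0
    calls_by_group: dict[str, list[BaseModCall]] = {}
    with pysam.AlignmentFile(path, reference_filename=reference) as bam:
        if contig not in bam.references:
            return [], 0, 0
        if region is not None:
            fetch = bam.fetch(region.chrom, region.start - 1, region.end)
        else:
            fetch = bam.fetch(contig)
        for read in fetch:
            if not _usable(read):
                continue
            n_reads += 1
            decoded = decode_alignment(read, contig)
            if decoded is None:
                continue
            n_tagged += 1
            if partition:
                if read.has_tag(tag_name):
                    label = f"{prefix}{read.get_tag(tag_name)}"
                elif include_ungrouped:
                    label = "ungrouped"
                else:
                    continue
                column = f"{sample}_{label}"
            else:
                column = sample
            calls_by_group.setdefault(column, []).extend(decoded)
    for column in sorted(calls_by_group):
        counts.extend(
            aggregate_cpg(
                calls_by_group[column],
                sites,
                mod_code=mod_code,
                mod_threshold=mod_threshold,
                min_confidence=min_confidence,
                sample=column,
                chrom=contig,
            )
        )
    return counts, n_reads, n_tagged


def bam_to_table(
    paths: Sequence[str | os.PathLike],
    reference: str | os.PathLike,
    sample_names: Sequence[str] | None = None,
    region: GenomicRegion | None = None,
    partition: bool = False,
    mod_code: str = "m",
    threads: int = 1,
    *,
    tag_name: str = "HP",
    prefix: str = "H",
    mod_threshold: float = 0.5,
    min_confidence: float = 0.0,
    include_ungrouped: bool = False,
) -> FrequencyTable:
    """Build a frequency table from modified-base-tagged BAM/CRAM files.

    One column per file, or per file x haplotype (suffixed ``_H1``/``_H2``)
    when ``partition`` is true. Work is spread over ``threads`` threads by
    (file, contig) pair; the result is assembled deterministically and is
    identical for any thread count.
    """
    paths = [os.fspath(p) for p in paths]
    reference = os.fspath(reference)
    if sample_names is None:
        sample_names = [
            os.path.basename(p).rsplit(".", 1)[0] for p in paths
        ]
    if len(sample_names) != len(paths):
        raise DataError(
            f"{len(sample_names)} sample names for {len(paths)} files"
        )
    if len(set(sample_names)) != len(sample_names):
        raise DataError(f"duplicate sample names: {sample_names}")
    if threads < 1:
        raise DataError("threads must be >= 1")

    tasks = []
    for path, sample in zip(paths, sample_names):
        with pysam.AlignmentFile(path, reference_filename=reference) as bam:
            contigs = (
                [region.chrom] if region is not None else list(bam.references)
            )
        for contig in contigs:
            tasks.append((path, contig, sample))

    def run(task):
        path, contig, sample = task
        return _process_contig(
            path,
            contig,
            reference,
            sample,
            region,
            partition,
            tag_name,
            prefix,
            mod_code,
            mod_threshold,
            min_confidence,
            include_ungrouped,
        )

    if threads == 1:
        results = [run(t) for t in tasks]
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(run, tasks))

    per_file_tagged: dict[str, int] = {p: 0 for p in paths}
    per_file_reads: dict[str, int] = {p: 0 for p in paths}
    all_counts: list[SiteCount] = []
    for (path, _, _), (counts, n_reads, n_tagged) in zip(tasks, results):
        all_counts.extend(counts)
        per_file_reads[path] += n_reads
        per_file_tagged[path] += n_tagged
    for path in paths:
        if per_file_reads[path] > 0 and per_file_tagged[path] == 0:
            raise NoModificationTagsError(
                f"{path}: no modification (MM/ML) tags found in any read"
            )
    return counts_to_table(all_counts)
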