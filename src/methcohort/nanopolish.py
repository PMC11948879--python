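"""Per-site frequencies from nanopolish methylation-caller output.

The caller emits one row per (read, CpG group) with a log-likelihood ratio
(LLR) of methylated vs unmethylated. Nearby CpGs whose states the model
cannot distinguish are called as one group (``num_motifs`` > 1) with a
shared LLR; the group's ``sequence`` context shows where the individual CG
dinucleotides sit. Converting to per-site frequencies follows the caller's
canonical helper: drop low-evidence rows (|LLR| below a cutoff), split each
group into its member CpGs — every member inherits the group call — and
count methylated / valid per position.

The caller writes 0-based coordinates; records are converted to 1-based on
parse so positions line up with the frequency-table convention. Motif
positions are already anchored to the forward-strand C for both sequencing
strands, so records simply pool per position.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import MalformedGroupError, SchemaError
from .tables import FrequencyTable, SiteCount, counts_to_table

#: Default evidence cutoff: groups with |LLR| < 2.0 are too ambiguous to call.
DEFAULT_LLR_CUTOFF = 2.0

REQUIRED_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "num_motifs",
    "sequence",
)

_CG = re.compile("CG")


@dataclass(frozen=True)
class NanopolishRecord:
    """One (read, CpG group) call. ``start`` is 1-based after parsing."""

    chrom: str
    strand: str
    start: int
    end: int
    read_name: str
    log_lik_ratio: float
    num_motifs: int
    sequence: str


def parse_nanopolish(path: str | os.PathLike) -> list[NanopolishRecord]:
    """Read a nanopolish methylation call TSV into typed records."""
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={"chromosome": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return [
        NanopolishRecord(
            chrom=row.chromosome,
            strand=row.strand,
            start=int(row.start) + 1,  # caller is 0-based
            end=int(row.end) + 1,
            read_name=row.read_name,
            log_lik_ratio=float(row.log_lik_ratio),
            num_motifs=int(row.num_motifs),
            sequence=row.sequence,
        )
        for row in df.itertuples(index=False)
    ]


def group_site_positions(record: NanopolishRecord) -> list[int]:
    """1-based reference positions of every CpG in a call group.

    The group anchor (``start``) is the first CG in ``sequence``; member
    k sits at start + (offset_k - offset_0).
    """
    offsets = [m.start() for m in _CG.finditer(record.sequence.upper())]
    if len(offsets) < record.num_motifs:
        raise MalformedGroupError(
            f"{record.read_name} at {record.chrom}:{record.start}: sequence "
            f"has {len(offsets)} CG motifs, expected {record.num_motifs}"
        )
    first = offsets[0]
    return [record.start + (off - first) for off in offsets[: record.num_motifs]]


def nanopolish_to_counts(
    records: Iterable[NanopolishRecord],
    llr_cutoff: float = DEFAULT_LLR_CUTOFF,
    *,
    sample: str = "sample",
) -> list[SiteCount]:
    """Aggregate call groups into per-CpG modified/valid counts."""
    if llr_cutoff <= 0:
        raise SchemaError(f"llr_cutoff must be > 0, got {llr_cutoff}")
    counters: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        if abs(rec.log_lik_ratio) < llr_cutoff:
            continue
        methylated = rec.log_lik_ratio > 0
        for pos in group_site_positions(rec):
            c = counters.setdefault((rec.chrom, pos), [0, 0])
            c[1] += 1
            if methylated:
                c[0] += 1
    return [
        SiteCount(chrom, pos, sample, n_mod, n_valid)
        for (chrom, pos), (n_mod, n_valid) in sorted(counters.items())
    ]


def nanopolish_to_table(
    paths: Sequence[str | os.PathLike],
    sample_names: Sequence[str] | None = None,
    llr_cutoff: float = DEFAULT_LLR_CUTOFF,
) -> FrequencyTable:
    """One frequency-table column per nanopolish call file."""
    paths = [os.fspath(p) for p in paths]
    if sample_names is None:
        sample_names = [os.path.basename(p).rsplit(".", 1)[0] for p in paths]
    counts: list[SiteCount] = []
    for path, sample in zip(paths, sample_names):
        counts.extend(
            nanopolish_to_counts(
                parse_nanopolish(path), llr_cutoff, sample=sample
            )
        )
    return counts_to_table(counts)
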