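"""GFF3 gene models for the heatmap's annotation track.

Builds the gene -> transcript -> exon hierarchy overlapping a query region
from a GFF3 file (plain or bgzip/gzip-compressed), resolving parent-child
links through ID/Parent attributes, and lays genes out in display rows so
overlapping genes never share a row. GENCODE and Ensembl dialects differ
in the middle tier's feature type (transcript, mRNA, ncRNA, ...); any
feature whose Parent is a gene is accepted as a transcript.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field

import gffutils

from .regions import GenomicRegion

logger = logging.getLogger(__name__)

_GENE_TYPES = {"gene", "pseudogene"}


@dataclass(frozen=True)
class Exon:
    start: int
    end: int


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    start: int
    end: int
    exons: tuple[Exon, ...]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: tuple[Transcript, ...]


@dataclass
class GeneTrack:
    region: GenomicRegion
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)


def _overlaps(start: int, end: int, region: GenomicRegion) -> bool:
    return start <= region.end and end >= region.start


def read_gff3(path: str | os.PathLike, region: GenomicRegion) -> GeneTrack:
    """Build the gene track for ``region`` from a GFF3 file.

    Only genes overlapping the region are kept; their transcripts and
    exons are kept in full (clipping is a display concern). Exons whose
    Parent cannot be resolved are dropped with a logged count. A gene's
    display name comes from ``Name=``, falling back to its ID.
    """
    path = os.fspath(path)
    opener = gzip.open if path.endswith((".gz", ".bgz")) else open
    with opener(path, "rt") as fh:
        data = fh.read()
    if not any(
        line and not line.startswith("#") for line in data.splitlines()
    ):
        return GeneTrack(region=region)
    db = gffutils.create_db(
        data, ":memory:", from_string=True, merge_strategy="create_unique"
    )

    genes: list[Gene] = []
    gene_ids: set[str] = set()
    for ftype in _GENE_TYPES:
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            feats = []
        for f in feats:
            if f.seqid != region.chrom or not _overlaps(f.start, f.end, region):
                continue
            gene_ids.add(f.id)

    n_orphans = 0
    for gid in sorted(gene_ids):
        gf = db[gid]
        transcripts: list[Transcript] = []
        for child in db.children(gf, level=1):
            # Liberal middle tier: anything whose Parent is the gene.
            exons = []
            for ex in db.children(child, level=1, featuretype="exon"):
                exons.append(Exon(ex.start, ex.end))
            exons.sort(key=lambda e: (e.start, e.end))
            transcripts.append(
                Transcript(child.id, child.start, child.end, tuple(exons))
            )
        transcripts.sort(key=lambda t: (t.start, t.end, t.transcript_id))
        name = gf.attributes.get("Name", [gid])[0]
        genes.append(
            Gene(
                gene_id=gid,
                name=name,
                chrom=gf.seqid,
                start=gf.start,
                end=gf.end,
                strand=gf.strand,
                transcripts=tuple(transcripts),
            )
        )

    # Count exons that name a Parent absent from the file.
    known = {f.id for f in db.all_features()}
    for f in db.features_of_type("exon"):
        parents = f.attributes.get("Parent", [])
        if parents and all(p not in known for p in parents):
            n_orphans += 1
    if n_orphans:
        logger.warning("dropped %d exon(s) with unresolvable Parent", n_orphans)

    genes.sort(key=lambda g: (g.start, g.gene_id))
    return GeneTrack(region=region, genes=genes)


def assign_rows(track: GeneTrack) -> dict[str, int]:
    """Greedy interval coloring: overlapping genes get distinct rows.

    Genes are processed sorted by (start, gene_id); each goes to the
    lowest-numbered row whose previous occupant it does not overlap, so
    the layout is deterministic and collision-free.
    """
    rows_end: list[int] = []
    assignment: dict[str, int] = {}
    for gene in sorted(track.genes, key=lambda g: (g.start, g.gene_id)):
        for row, last_end in enumerate(rows_end):
            if gene.start > last_end:
                rows_end[row] = gene.end
                assignment[gene.gene_id] = row
                break
        else:
            rows_end.append(gene.end)
            assignment[gene.gene_id] = len(rows_end) - 1
    return assignment
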