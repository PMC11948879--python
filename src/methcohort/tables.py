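"""The modification-frequency table model and its indexed on-disk dialect.

A frequency table is a matrix of per-position, per-sample modification
frequencies: one row per genomic position, one column per individual or
haplotype, cells in [0, 1] with an explicit missing state. On disk it is a
block-gzipped TSV (``chrom<TAB>position<TAB><sample...>``) with a tabix
index over (chrom, position), so a genomic region of a cohort-scale table
can be pulled out without scanning the file.

In memory the matrix is a pandas DataFrame with a (chrom, position)
MultiIndex; missing cells are NaN. Rows are kept sorted by chromosome
(natural order: chr2 < chr10) and position, with duplicate positions
treated as a pipeline bug rather than silently merged.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import (
    DataError,
    MissingIndexError,
    TableConflictError,
    TableParseError,
)
from .regions import CHROM_END, GenomicRegion

#: Default chunk size for the cohort split/merge pipeline (bp).
DEFAULT_CHUNK_BP = 25_000_000

#: Decimal places used when serializing frequencies.
_DECIMALS = 4

_NA_STRINGS = frozenset({"", "NA", "nan", "NaN"})

_NUM_RE = re.compile(r"(\d+)")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key giving natural chromosome order: chr2 < chr10 < chrX."""
    return tuple(
        int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(chrom)
    )


@dataclass(frozen=True)
class SiteCount:
    """Per-(position, sample) modification evidence: counts, not a ratio.

    ``frequency`` is n_modified / n_valid; a site with zero valid calls is
    simply absent (missing) for that sample rather than carried as 0/0.
    """

    chrom: str
    position: int  # 1-based
    sample: str
    n_modified: int
    n_valid: int

    def __post_init__(self) -> None:
        if self.n_modified < 0 or self.n_valid < self.n_modified:
            raise DataError(
                f"invalid counts at {self.chrom}:{self.position} "
                f"({self.sample}): {self.n_modified}/{self.n_valid}"
            )

    @property
    def frequency(self) -> float:
        if self.n_valid == 0:
            return float("nan")
        return self.n_modified / self.n_valid


class FrequencyTable:
    """An in-memory modification-frequency matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by a (chrom, position) MultiIndex, one float
        column per sample, NaN marking missing cells.
    """

    def __init__(self, data: pd.DataFrame, *, validate: bool = True):
        if not isinstance(data.index, pd.MultiIndex) or data.index.nlevels != 2:
            raise TableParseError("expected a (chrom, position) MultiIndex")
        data = data.astype(float)
        data.index = data.index.set_names(["chrom", "position"])
        data = _sort_genomic(data)
        if validate:
            self._validate(data)
        self.data = data

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        if data.columns.duplicated().any():
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise TableParseError(f"duplicate sample names: {dupes}")
        if data.index.duplicated().any():
            first = data.index[data.index.duplicated()][0]
            raise TableParseError(
                f"duplicate position {first[0]}:{first[1]} in table"
            )
        with np.errstate(invalid="ignore"):
            vals = data.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            chrom, pos = data.index[i]
            raise TableParseError(
                f"frequency outside [0,1] at {chrom}:{pos} "
                f"({data.columns[j]}): {vals[i, j]}"
            )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        sites: Sequence[tuple[str, int]],
        samples: Sequence[str],
        values: np.ndarray,
    ) -> "FrequencyTable":
        idx = pd.MultiIndex.from_tuples(sites, names=["chrom", "position"])
        return cls(pd.DataFrame(np.asarray(values, float), idx, list(samples)))

    @classmethod
    def empty(cls, samples: Sequence[str] = ()) -> "FrequencyTable":
        idx = pd.MultiIndex.from_arrays([[], []], names=["chrom", "position"])
        return cls(pd.DataFrame(columns=list(samples), index=idx, dtype=float))

    # -- basic properties -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sites(self) -> list[tuple[str, int]]:
        return list(self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        if self.samples != other.samples or self.sites != other.sites:
            return False
        a, b = self.data.to_numpy(float), other.data.to_numpy(float)
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())

    def __repr__(self) -> str:
        return (
            f"FrequencyTable({self.n_sites} sites x "
            f"{len(self.samples)} samples)"
        )

    # -- operations -------------------------------------------------------

    def subset(self, region: GenomicRegion) -> "FrequencyTable":
        """Rows falling inside ``region`` (linear scan; no index needed)."""
        chroms = self.data.index.get_level_values(0)
        pos = self.data.index.get_level_values(1)
        mask = (
            (chroms == region.chrom)
            & (pos >= region.start)
            & (pos <= region.end)
        )
        return FrequencyTable(self.data.loc[mask], validate=False)

    def select(self, samples: Sequence[str]) -> "FrequencyTable":
        return FrequencyTable(self.data[list(samples)], validate=False)


def _sort_genomic(data: pd.DataFrame) -> pd.DataFrame:
    if len(data) <= 1:
        return data
    order = sorted(
        range(len(data)),
        key=lambda i: (natural_chrom_key(data.index[i][0]), data.index[i][1]),
    )
    if order == list(range(len(data))):
        return data
    return data.iloc[order]


def missing_fraction(table: FrequencyTable) -> "pd.Series":
    """Fraction of missing cells per column (sample -> value in [0, 1])."""
    if table.n_sites == 0:
        raise DataError("missing_fraction undefined on a table with no sites")
    return table.data.isna().sum() / table.n_sites


# ---------------------------------------------------------------------------
# On-disk dialect
# ---------------------------------------------------------------------------


def _open_text(path: str):
    # bgzip is gzip-compatible, so gzip.open covers .gz/.bgz as well.
    if str(path).endswith((".gz", ".bgz")):
        import gzip

        return gzip.open(path, "rt")
    return open(path, "rt")


def read_table(
    path: str | os.PathLike, region: GenomicRegion | None = None
) -> FrequencyTable:
    """Read a frequency-table TSV (plain or gzipped).

    The reader is liberal about the missing-value spelling ("", "NA",
    "nan") and tolerates unsorted rows; the invariants (sorted, unique
    positions, values in [0, 1]) are enforced on the result. Parse errors
    carry 1-based line numbers.
    """
    path = os.fspath(path)
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TableParseError(f"{path}: empty file (no header)")
        fields = header.split("\t")
        if len(fields) < 2:
            raise TableParseError(
                f"{path}: malformed header (need chrom, position columns)"
            )
        samples = fields[2:]
        if len(set(samples)) != len(samples):
            raise TableParseError(f"{path}: duplicate sample names in header")
        sites: list[tuple[str, int]] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(fields):
                raise TableParseError(
                    f"{path}:{lineno}: expected {len(fields)} fields, "
                    f"got {len(parts)}"
                )
            chrom = parts[0]
            try:
                pos = int(parts[1])
            except ValueError:
                raise TableParseError(
                    f"{path}:{lineno}: non-numeric position {parts[1]!r}"
                ) from None
            if region is not None and not region.contains(chrom, pos):
                continue
            row: list[float] = []
            for name, cell in zip(samples, parts[2:]):
                if cell in _NA_STRINGS:
                    row.append(np.nan)
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    raise TableParseError(
                        f"{path}:{lineno}: non-numeric frequency {cell!r} "
                        f"in column {name}"
                    ) from None
                if not 0.0 <= v <= 1.0:
                    raise TableParseError(
                        f"{path}:{lineno}: frequency {v} outside [0,1] "
                        f"in column {name}"
                    )
                row.append(v)
            sites.append((chrom, pos))
            rows.append(row)
    if not sites:
        return FrequencyTable.empty(samples)
    return FrequencyTable.from_records(sites, samples, np.array(rows))


def format_table(table: FrequencyTable) -> str:
    """Serialize to the canonical dialect (4-decimal frequencies)."""
    lines = ["\t".join(["chrom", "position", *table.samples])]
    vals = table.data.to_numpy(float)
    for i, (chrom, pos) in enumerate(table.sites):
        cells = [
            "" if np.isnan(v) else f"{v:.{_DECIMALS}f}" for v in vals[i]
        ]
        lines.append("\t".join([chrom, str(pos), *cells]))
    return "\n".join(lines) + "\n"


def write_table(
    table: FrequencyTable, path: str | os.PathLike, index: bool = True
) -> str | None:
    """Write a block-gzipped TSV; optionally tabix-index it.

    Returns the index path when ``index=True``, else None. The index maps
    column 1 as the sequence and column 2 as both start and end (1-based),
    skipping the single header line.
    """
    path = os.fspath(path)
    text = format_table(table)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".", suffix=".tsv")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        pysam.tabix_compress(tmp, path, force=True)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)
    if not index:
        return None
    pysam.tabix_index(
        path,
        seq_col=0,
        start_col=1,
        end_col=1,
        line_skip=1,
        zerobased=False,
        force=True,
    )
    return path + ".tbi"


def query_region(
    path: str | os.PathLike, region: GenomicRegion
) -> FrequencyTable:
    """Fetch exactly the rows inside ``region`` from an indexed table."""
    path = os.fspath(path)
    if not (os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")):
        raise MissingIndexError(
            f"{path} has no tabix index; re-write it with index=True"
        )
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise TableParseError(f"{path}: missing header line")
    samples = header.split("\t")[2:]
    with pysam.TabixFile(path) as tbx:
        if region.chrom not in tbx.contigs:
            return FrequencyTable.empty(samples)
        end = min(region.end, CHROM_END - 1)
        sites: list[tuple[str, int]] = []
        rows: list[list[float]] = []
        for line in tbx.fetch(region.chrom, region.start - 1, end):
            parts = line.split("\t")
            sites.append((parts[0], int(parts[1])))
            rows.append(
                [
                    np.nan if cell in _NA_STRINGS else float(cell)
                    for cell in parts[2:]
                ]
            )
    if not sites:
        return FrequencyTable.empty(samples)
    return FrequencyTable.from_records(sites, samples, np.array(rows))


# ---------------------------------------------------------------------------
# Cohort split / merge pipeline semantics
# ---------------------------------------------------------------------------


def merge_tables(parts: Iterable[FrequencyTable]) -> FrequencyTable:
    """Union of sites and columns across parts, sorted genomically.

    Parts may repeat a column only over disjoint position ranges (the
    chunked-pipeline case); two non-missing values for the same cell that
    disagree raise :class:`TableConflictError` naming the cell.
    """
    parts = list(parts)
    if not parts:
        return FrequencyTable.empty()
    frames = [p.data for p in parts]
    union_idx = frames[0].index
    for f in frames[1:]:
        union_idx = union_idx.union(f.index)
    columns: list[str] = []
    for f in frames:
        for c in f.columns:
            if c not in columns:
                columns.append(c)
    out = pd.DataFrame(np.nan, index=union_idx, columns=columns)
    for f in frames:
        for c in f.columns:
            incoming = f[c].reindex(union_idx)
            existing = out[c]
            both = incoming.notna() & existing.notna()
            if both.any():
                clash = both & (incoming != existing)
                if clash.any():
                    chrom, pos = union_idx[clash][0]
                    raise TableConflictError(
                        f"conflicting values for {chrom}:{pos} column {c}: "
                        f"{existing[clash].iloc[0]} vs {incoming[clash].iloc[0]}"
                    )
            out[c] = existing.where(incoming.isna(), incoming)
    return FrequencyTable(out, validate=False)


def split_table(
    table: FrequencyTable, chunk_bp: int = DEFAULT_CHUNK_BP
) -> list[FrequencyTable]:
    """Split into fixed genomic windows of ``chunk_bp`` per chromosome.

    Window k covers positions [k*chunk_bp + 1, (k+1)*chunk_bp], so the
    genomic span inside any chunk is strictly less than ``chunk_bp``.
    Chunks partition the rows; empty windows are not emitted.
    """
    if chunk_bp < 1:
        raise DataError(f"chunk_bp must be >= 1, got {chunk_bp}")
    if table.n_sites == 0:
        return [table]
    chroms = table.data.index.get_level_values(0)
    pos = table.data.index.get_level_values(1).to_numpy()
    window = (pos - 1) // chunk_bp
    keys = pd.MultiIndex.from_arrays([chroms, window])
    chunks = []
    seen = []
    for key in keys:
        if key not in seen:
            seen.append(key)
    for chrom, win in sorted(seen, key=lambda k: (natural_chrom_key(k[0]), k[1])):
        mask = (chroms == chrom) & (window == win)
        chunks.append(FrequencyTable(table.data.loc[mask], validate=False))
    return chunks


def counts_to_table(counts: Iterable[SiteCount]) -> FrequencyTable:
    """Assemble per-(site, sample) counts into a frequency table.

    Sites with zero valid calls for a sample stay missing; a site absent
    from every sample produces no row.
    """
    cells: dict[tuple[str, int], dict[str, float]] = {}
    samples: list[str] = []
    for sc in counts:
        if sc.n_valid == 0:
            continue
        if sc.sample not in samples:
            samples.append(sc.sample)
        row = cells.setdefault((sc.chrom, sc.position), {})
        if sc.sample in row:
            raise TableConflictError(
                f"duplicate counts for {sc.chrom}:{sc.position} "
                f"sample {sc.sample}"
            )
        row[sc.sample] = sc.frequency
    if not cells:
        return FrequencyTable.empty(samples)
    sites = list(cells)
    values = np.full((len(sites), len(samples)), np.nan)
    col = {s: j for j, s in enumerate(samples)}
    for i, site in enumerate(sites):
        for s, v in cells[site].items():
            values[i, col[s]] = v
    return FrequencyTable.from_records(sites, samples, values)
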