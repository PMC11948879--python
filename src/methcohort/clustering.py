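"""Hierarchical clustering of samples/haplotypes with the missing-data protocol.

Methylation matrices from real cohorts are gappy: coverage varies, and
haplotype partitioning halves it. Clustering therefore runs a fixed
four-step protocol:

1. ``filter_missing`` — drop columns with >= 40% missing cells (inclusive
   boundary: exactly 40% is dropped), so mostly-empty haplotypes cannot
   distort the tree.
2. ``impute_linear`` — fill interior gaps per column by linear
   interpolation *in genomic position* (closer positions get more weight),
   justified by the local coregulation of methylation. Leading/trailing
   gaps have only one neighbor and are left missing, never extrapolated.
3. ``drop_residual`` — remove columns still containing missing cells.
4. ``cluster_samples`` — complete-linkage agglomeration on Euclidean
   distances between column vectors (frequencies share units, so no
   standardization), with a deterministic leaf order: at every merge the
   subtree containing the lexicographically smallest original label goes
   left.

The displayed heatmap shows the imputed matrix, not the raw one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .errors import DataError, NothingToClusterError
from .tables import FrequencyTable, missing_fraction

#: Columns with at least this fraction of missing cells are removed.
DEFAULT_MAX_MISSING = 0.40


@dataclass
class ClusterResult:
    """Outcome of the full protocol.

    ``kept_samples`` is in dendrogram leaf order (left to right);
    ``merge_tree`` uses scipy node ids (leaves 0..n-1 index the kept
    samples in their pre-clustering column order, internal node n+i is
    created by merge step i).
    """

    kept_samples: list[str]
    removed_pre: list[str]
    removed_post: list[str]
    imputed: FrequencyTable
    merge_tree: list[tuple[int, int, float]]
    leaf_labels: list[str]  # label of leaf id i (pre-clustering order)

    @property
    def n_samples(self) -> int:
        return len(self.kept_samples)


def filter_missing(
    table: FrequencyTable, max_missing: float = DEFAULT_MAX_MISSING
) -> tuple[FrequencyTable, list[str]]:
    """Remove columns whose missing fraction is >= ``max_missing``."""
    if not 0 < max_missing <= 1:
        raise DataError(f"max_missing must be in (0, 1], got {max_missing}")
    frac = missing_fraction(table)
    removed = [s for s in table.samples if frac[s] >= max_missing]
    kept = [s for s in table.samples if s not in removed]
    if not kept:
        raise NothingToClusterError(
            "every column exceeds the missingness threshold; nothing to cluster"
        )
    return table.select(kept), removed


def impute_linear(table: FrequencyTable) -> FrequencyTable:
    """Fill interior missing cells by position-weighted linear interpolation.

    A gap at position p between observed neighbors (p0, v0) and (p1, v1)
    becomes v0 + (v1 - v0) * (p - p0) / (p1 - p0). Interpolation never
    crosses a chromosome boundary; observed cells are untouched; edge gaps
    stay missing. Idempotent.
    """
    pieces = []
    for _, group in table.data.groupby(level="chrom", sort=False):
        block = group.droplevel("chrom")
        filled = block.interpolate(
            method="index", limit_area="inside", axis=0
        )
        filled.index = group.index
        pieces.append(filled)
    out = pd.concat(pieces) if pieces else table.data
    return FrequencyTable(out, validate=False)


def drop_residual(
    table: FrequencyTable,
) -> tuple[FrequencyTable, list[str]]:
    """Remove columns still containing any missing cell."""
    has_gap = table.data.isna().any()
    removed = [s for s in table.samples if has_gap[s]]
    kept = [s for s in table.samples if not has_gap[s]]
    if not kept:
        raise NothingToClusterError(
            "every column retains missing values after interpolation"
        )
    return table.select(kept), removed


def _leaf_order(
    merge_tree: list[tuple[int, int, float]], labels: list[str]
) -> list[int]:
    """Left-to-right leaves; smaller-min-label subtree goes left."""
    n = len(labels)
    min_label: dict[int, str] = {i: labels[i] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, (a, b, _) in enumerate(merge_tree):
        node = n + step
        children[node] = (a, b)
        min_label[node] = min(min_label[a], min_label[b])

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        if min_label[a] <= min_label[b]:
            return leaves(a) + leaves(b)
        return leaves(b) + leaves(a)

    root = n + len(merge_tree) - 1 if merge_tree else 0
    return leaves(root)


def cluster_samples(table: FrequencyTable) -> ClusterResult:
    """Complete-linkage clustering of a complete (no-missing) matrix."""
    if len(table.samples) < 2:
        raise NothingToClusterError(
            f"need at least 2 columns to cluster, have {len(table.samples)}"
        )
    if bool(table.data.isna().any().any()):
        raise DataError("cluster_samples requires a matrix with no missing cells")
    matrix = table.data.to_numpy(float).T  # samples x sites
    labels = table.samples
    dists = pdist(matrix, metric="euclidean")
    z = linkage(dists, method="complete")
    merge_tree = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    order = _leaf_order(merge_tree, labels)
    kept = [labels[i] for i in order]
    return ClusterResult(
        kept_samples=kept,
        removed_pre=[],
        removed_post=[],
        imputed=table.select(kept),
        merge_tree=merge_tree,
        leaf_labels=labels,
    )


def root_split(result: ClusterResult) -> tuple[set[str], set[str]]:
    """Sample labels on either side of the dendrogram's root merge."""
    n = len(result.leaf_labels)
    if not result.merge_tree:
        return set(result.leaf_labels), set()
    children: dict[int, tuple[int, int]] = {
        n + i: (int(a), int(b))
        for i, (a, b, _) in enumerate(result.merge_tree)
    }

    def leaves(node: int) -> set[str]:
        if node < n:
            return {result.leaf_labels[node]}
        a, b = children[node]
        return leaves(a) | leaves(b)

    a, b = children[n + len(result.merge_tree) - 1]
    return leaves(a), leaves(b)


def cluster_table(
    table: FrequencyTable, max_missing: float = DEFAULT_MAX_MISSING
) -> ClusterResult:
    """The full protocol: filter -> interpolate -> drop residual -> cluster."""
    filtered, removed_pre = filter_missing(table, max_missing)
    imputed = impute_linear(filtered)
    complete, removed_post = drop_residual(imputed)
    result = cluster_samples(complete)
    result.removed_pre = removed_pre
    result.removed_post = removed_post
    return result
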