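"""Region heatmap figure: matrix + optional dendrogram + gene track.

The figure document is a plain data object; rendering writes a
self-contained HTML file containing (a) the full matrix as a JSON payload
(so the displayed data can be read back programmatically) and (b) an
inline SVG drawing: genomic positions run top to bottom, samples left to
right, cells colored on a fixed purple(0) -> yellow(1) viridis ramp
regardless of the data range, missing cells light gray. Gene models sit in
a left-hand panel aligned to the position axis; the dendrogram sits above
the columns. Hover text (chrom:pos, sample, frequency) rides on SVG
``<title>`` elements. Rendering is a pure function of the document, so the
same figure always produces byte-identical output.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import to_hex

from .annotation import GeneTrack, assign_rows
from .clustering import ClusterResult
from .errors import ConsistencyError, DataError
from .tables import FrequencyTable

_VIRIDIS = colormaps["viridis"]
MISSING_COLOR = "#d3d3d3"

# Layout constants (SVG user units).
_CELL_W = 14
_CELL_H = 6
_TRACK_W = 110
_DENDRO_H = 90
_LABEL_H = 80
_PAD = 10


def value_color(v: float) -> str:
    """Fixed-domain [0,1] purple->yellow ramp; NaN maps to light gray."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING_COLOR
    return to_hex(_VIRIDIS(min(max(float(v), 0.0), 1.0)))


@dataclass
class FigureDoc:
    """Everything needed to draw the figure, display-ordered."""

    sites: list[tuple[str, int]]  # rows, ascending genomic order
    samples: list[str]  # columns, display order
    values: np.ndarray  # (n_sites, n_samples), NaN = missing
    title: str = "Modification frequencies"
    track: GeneTrack | None = None
    cluster: ClusterResult | None = None


def build_figure(
    table: FrequencyTable,
    track: GeneTrack | None = None,
    cluster: ClusterResult | None = None,
    title: str = "Modification frequencies",
) -> FigureDoc:
    """Compose the figure document.

    With a clustering result, the heatmap shows the *imputed* matrix in
    dendrogram leaf order; otherwise the raw table in input column order.
    """
    if table.n_sites == 0:
        raise DataError("cannot build a figure from an empty table")
    if cluster is not None:
        unknown = set(cluster.kept_samples) - set(table.samples)
        if unknown:
            raise ConsistencyError(
                f"clustered samples absent from table: {sorted(unknown)}"
            )
        display = cluster.imputed.select(cluster.kept_samples)
    else:
        display = table
    return FigureDoc(
        sites=display.sites,
        samples=display.samples,
        values=display.data.to_numpy(float),
        title=title,
        track=track,
        cluster=cluster,
    )


# ---------------------------------------------------------------------------
# SVG assembly
# ---------------------------------------------------------------------------


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _heatmap_svg(fig: FigureDoc, x0: float, y0: float) -> list[str]:
    parts = []
    for i, (chrom, pos) in enumerate(fig.sites):
        y = y0 + i * _CELL_H
        for j, sample in enumerate(fig.samples):
            v = fig.values[i, j]
            label = "missing" if math.isnan(v) else f"{v:.4f}"
            parts.append(
                f'<rect class="cell" x="{x0 + j * _CELL_W}" y="{y}" '
                f'width="{_CELL_W}" height="{_CELL_H}" fill="{value_color(v)}">'
                f"<title>{_esc(chrom)}:{pos} {_esc(sample)} {label}</title>"
                f"</rect>"
            )
    return parts


def _dendrogram_svg(fig: FigureDoc, x0: float, y0: float) -> list[str]:
    """Elbow links above the columns, root at the top."""
    cluster = fig.cluster
    if cluster is None or not cluster.merge_tree:
        return []
    n = len(cluster.leaf_labels)
    col_of = {s: j for j, s in enumerate(fig.samples)}
    # Node coordinates: x = center over member columns, y = merge height.
    xs = {i: x0 + (col_of[cluster.leaf_labels[i]] + 0.5) * _CELL_W for i in range(n)}
    ys = {i: 0.0 for i in range(n)}
    max_h = max(h for _, _, h in cluster.merge_tree) or 1.0
    parts = []
    for step, (a, b, h) in enumerate(cluster.merge_tree):
        node = n + step
        xs[node] = (xs[a] + xs[b]) / 2.0
        ys[node] = h
        ya = y0 + _DENDRO_H * (1 - ys[a] / max_h)
        yb = y0 + _DENDRO_H * (1 - ys[b] / max_h)
        yh = y0 + _DENDRO_H * (1 - h / max_h)
        pts = (
            f"{xs[a]:.2f},{ya:.2f} {xs[a]:.2f},{yh:.2f} "
            f"{xs[b]:.2f},{yh:.2f} {xs[b]:.2f},{yb:.2f}"
        )
        parts.append(
            f'<polyline class="dendro" points="{pts}" fill="none" '
            f'stroke="#444444" stroke-width="1"/>'
        )
    return parts


def _track_svg(fig: FigureDoc, x0: float, y0: float) -> list[str]:
    """Vertical gene models aligned to the heatmap's position axis."""
    track = fig.track
    if track is None or not track.genes:
        return []
    positions = np.array([p for _, p in fig.sites], float)
    rows_idx = np.arange(len(positions), dtype=float)

    def y_of(genomic: float) -> float:
        row = float(np.interp(genomic, positions, rows_idx))
        return y0 + (row + 0.5) * _CELL_H

    lanes = assign_rows(track)
    n_lanes = max(lanes.values()) + 1
    lane_w = _TRACK_W / max(n_lanes, 1)
    lo, hi = positions[0], positions[-1]
    parts = []
    for gene in track.genes:
        gx = x0 + lanes[gene.gene_id] * lane_w + lane_w / 2
        g_top = y_of(max(gene.start, lo))
        g_bot = y_of(min(gene.end, hi))
        parts.append(
            f'<line class="gene" x1="{gx:.2f}" y1="{g_top:.2f}" '
            f'x2="{gx:.2f}" y2="{g_bot:.2f}" stroke="#1f77b4" '
            f'stroke-width="1.5"><title>{_esc(gene.name)} '
            f'({_esc(gene.strand)})</title></line>'
        )
        for tr in gene.transcripts:
            for ex in tr.exons:
                if ex.end < lo or ex.start > hi:
                    continue
                e_top = y_of(max(ex.start, lo))
                e_bot = y_of(min(ex.end, hi))
                height = max(e_bot - e_top, 1.0)
                parts.append(
                    f'<rect class="exon" x="{gx - lane_w * 0.3:.2f}" '
                    f'y="{e_top:.2f}" width="{lane_w * 0.6:.2f}" '
                    f'height="{height:.2f}" fill="#1f77b4"/>'
                )
        parts.append(
            f'<text class="gene-label" x="{gx:.2f}" y="{g_top - 3:.2f}" '
            f'font-size="7" text-anchor="middle">{_esc(gene.name)}</text>'
        )
    return parts


def figure_svg(fig: FigureDoc) -> str:
    has_track = fig.track is not None and len(fig.track.genes) > 0
    has_dendro = fig.cluster is not None and bool(fig.cluster.merge_tree)
    x_heat = _PAD + (_TRACK_W + _PAD if has_track else 0)
    y_heat = _PAD + (_DENDRO_H + _PAD if has_dendro else 0)
    width = x_heat + len(fig.samples) * _CELL_W + _PAD
    height = y_heat + len(fig.sites) * _CELL_H + _LABEL_H + _PAD
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f"<title>{_esc(fig.title)}</title>",
    ]
    parts.extend(_heatmap_svg(fig, x_heat, y_heat))
    if has_dendro:
        parts.extend(_dendrogram_svg(fig, x_heat, _PAD))
    if has_track:
        parts.extend(_track_svg(fig, _PAD, y_heat))
    y_labels = y_heat + len(fig.sites) * _CELL_H + 8
    for j, sample in enumerate(fig.samples):
        x = x_heat + (j + 0.5) * _CELL_W
        parts.append(
            f'<text class="col-label" x="{x}" y="{y_labels}" font-size="6" '
            f'text-anchor="end" transform="rotate(-90 {x} {y_labels})">'
            f"{_esc(sample)}</text>"
        )
    parts.append("</svg>")
    return "\n".join(parts)


def figure_payload(fig: FigureDoc) -> dict:
    """The matrix as plain JSON-compatible data (nulls for missing)."""
    return {
        "title": fig.title,
        "chrom": [c for c, _ in fig.sites],
        "position": [p for _, p in fig.sites],
        "samples": list(fig.samples),
        "values": [
            [None if math.isnan(v) else round(float(v), 6) for v in row]
            for row in fig.values
        ],
    }


def render_html(fig: FigureDoc, path: str | os.PathLike) -> None:
    """Write a self-contained HTML document for the figure."""
    payload = json.dumps(figure_payload(fig), separators=(",", ":"))
    html = "\n".join(
        [
            "<!DOCTYPE html>",
            '<html lang="en">',
            '<head><meta charset="utf-8"/>',
            f"<title>{_esc(fig.title)}</title></head>",
            "<body>",
            f"<h1>{_esc(fig.title)}</h1>",
            figure_svg(fig),
            f'<script type="application/json" id="methcohort-data">{payload}</script>',
            "</body>",
            "</html>",
            "",
        ]
    )
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        fh.write(html)


def extract_payload(html_path: str | os.PathLike) -> dict:
    """Read back the JSON matrix embedded by :func:`render_html`."""
    with open(os.fspath(html_path), "r", encoding="utf-8") as fh:
        text = fh.read()
    marker = 'id="methcohort-data">'
    start = text.index(marker) + len(marker)
    end = text.index("</script>", start)
    return json.loads(text[start:end])
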