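"""Renderers for the core linked views.

Each renderer is a pure function from data (+ orders, colors and the
current :class:`~omiclink.datamodel.Selection`) to a :class:`Scene`.
Highlighting follows one convention throughout: a primitive whose object
is selected carries ``highlighted=True``, and bar-shaped views draw the
selected fraction of each bar as a sub-bar — the linked-highlighting
convention of interactive statistical graphics.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..compare import ConfusionMatrix
from ..datamodel import FeatureMatrix, Selection, StateMatrix
from ..unsupervised import Dendrogram
from .scene import MISSING_COLOR, STATE_COLORS, DivergingScale, Scene

logger = logging.getLogger(__name__)

__all__ = ["render_heatmap", "render_dendrogram", "render_barchart",
           "render_histogram", "render_eventchart",
           "render_correlation_matrix", "render_confusion"]

CELL = 10.0  # default cell size in px


def _sel(selection: Selection | None) -> Selection:
    return selection if selection is not None else Selection()


def _row_selection(matrix, selection: Selection) -> frozenset[str]:
    # expression rows are genes, copy-number rows are markers
    return selection.markers if isinstance(matrix, StateMatrix) else selection.genes


def _check_order(order, n, what):
    if order is None:
        return list(range(n))
    order = [int(i) for i in order]
    if sorted(order) != list(range(n)):
        raise ValueError(f"{what} order must be a permutation of 0..{n - 1}")
    return order


def render_heatmap(matrix: FeatureMatrix, row_order=None, col_order=None,
                   colorscale=None, annotations=None,
                   selection: Selection | None = None, cell: float = CELL) -> Scene:
    """Heatmap of an expression or copy-number matrix.

    One rect per cell (missing cells included, in the missing color),
    provenance ``"row|col"``.  ``annotations`` is a list of
    ``(name, sample → class, class → color)`` bars drawn above the matrix
    — the carrier of clinical color codes into the heatmap.  Selected
    rows/columns have their cells flagged.
    """
    sel = _sel(selection)
    row_order = _check_order(row_order, len(matrix.row_ids), "row")
    col_order = _check_order(col_order, len(matrix.col_ids), "column")
    annotations = annotations or []
    if colorscale is None:
        if isinstance(matrix, StateMatrix):
            colorscale = lambda v: (MISSING_COLOR if np.isnan(v) else STATE_COLORS[float(v)])
        else:
            colorscale = DivergingScale.from_matrix(matrix.values)
    sel_rows = _row_selection(matrix, sel)
    top = cell * len(annotations)
    scene = Scene(width=cell * len(col_order),
                  height=top + cell * len(row_order))
    for a, (name, sample_class, class_colors) in enumerate(annotations):
        for x, j in enumerate(col_order):
            sid = matrix.col_ids[j]
            cls = sample_class.get(sid)
            color = class_colors.get(cls, MISSING_COLOR)
            scene.add("rect", (x * cell, a * cell, cell, cell), color,
                      provenance=f"{name}:{sid}", highlighted=sid in sel.samples)
    for y, i in enumerate(row_order):
        rid = matrix.row_ids[i]
        for x, j in enumerate(col_order):
            cid = matrix.col_ids[j]
            v = matrix.values[i, j]
            scene.add("rect", (x * cell, top + y * cell, cell, cell),
                      colorscale(v), provenance=f"{rid}|{cid}",
                      highlighted=rid in sel_rows or cid in sel.samples)
    return scene


def _node_positions(dend: Dendrogram, cell: float):
    """x of every node (leaf centers per leaf order, parents at child midpoints)."""
    order = dend.leaf_order
    pos = {int(leaf): (p + 0.5) * cell for p, leaf in enumerate(order)}
    x: dict[int, float] = dict(pos)
    for i, (a, b, h) in enumerate(dend.merges):
        x[dend.n + i] = (x[a] + x[b]) / 2.0
    return x


def render_dendrogram(dend: Dendrogram, orientation: str = "top",
                      selection: Selection | None = None, cell: float = CELL,
                      depth: float = 100.0) -> Scene:
    """Rectangular dendrogram; leaf x-positions equal heatmap cell centers
    when drawn with the same ``cell`` and a matching leaf order.

    A merge bracket is highlighted when every leaf beneath it is selected,
    so selecting a cluster highlights its whole subtree.
    """
    sel = _sel(selection)
    selected_items = sel.genes | sel.samples | sel.markers
    n = dend.n
    hmax = max((h for _, _, h in dend.merges), default=1.0) or 1.0
    x = _node_positions(dend, cell)
    y = {i: depth for i in range(n)}  # leaves sit on the baseline
    members: dict[int, set[str]] = {i: {dend.item_ids[i]} for i in range(n)}
    scene = Scene(width=cell * n, height=depth)
    for i, (a, b, h) in enumerate(dend.merges):
        node = n + i
        y[node] = depth * (1.0 - h / hmax)
        members[node] = members[a] | members[b]
        pts = ((x[a], y[a]), (x[a], y[node]), (x[b], y[node]), (x[b], y[b]))
        scene.add("polyline", pts, "#333333", provenance=f"merge{i}",
                  highlighted=bool(members[node]) and members[node] <= selected_items)
    if orientation not in ("top", "left"):
        raise ValueError("orientation must be 'top' or 'left'")
    if orientation == "left":  # swap axes for a row dendrogram
        scene = _transpose_scene(scene)
    return scene


def _transpose_scene(scene: Scene) -> Scene:
    out = Scene(width=scene.height, height=scene.width)
    for p in scene.primitives:
        if p.kind == "polyline":
            geom = tuple((y, x) for x, y in p.geometry)
        elif p.kind == "rect":
            x, y, w, h = p.geometry
            geom = (y, x, h, w)
        else:
            x1, y1, x2, y2 = p.geometry
            geom = (y1, x1, y2, x2)
        out.add(p.kind, geom, p.color, p.provenance, p.highlighted)
    return out


def _bar_order(counts: Mapping, order: str):
    keys = list(counts)
    if order == "as-given":
        return keys
    if order == "by-count":
        return sorted(keys, key=lambda k: (-counts[k], keys.index(k)))
    if order == "by-label":
        return sorted(keys, key=str)
    raise ValueError(f"unknown bar order {order!r}")


def render_barchart(counts: Mapping, order: str = "as-given",
                    colors: Mapping | None = None,
                    selected_counts: Mapping | None = None,
                    bar_width: float = 20.0, max_height: float = 100.0) -> Scene:
    """Barchart of categorical counts, one bar per class, height ∝ count.

    The selected fraction of each class is drawn as a flagged sub-bar of
    proportional height rising from the baseline.  An empty class list
    yields an empty scene.
    """
    keys = _bar_order(counts, order)
    scene = Scene(width=bar_width * len(keys), height=max_height)
    if not keys:
        return scene
    peak = max(counts[k] for k in keys) or 1
    colors = colors or {}
    selected_counts = selected_counts or {}
    for i, k in enumerate(keys):
        h = max_height * counts[k] / peak
        color = colors.get(k, "#999999")
        scene.add("rect", (i * bar_width, max_height - h, bar_width, h), color,
                  provenance=f"class:{k}")
        nsel = min(selected_counts.get(k, 0), counts[k])
        if nsel:
            hs = h * nsel / counts[k]
            scene.add("rect", (i * bar_width, max_height - hs, bar_width, hs),
                      color, provenance=f"class:{k}", highlighted=True)
    return scene


def histogram_counts(values, binwidth: float, anchor: float = 0.0):
    """Half-open binning [anchor + k·w, anchor + (k+1)·w); returns
    (bin start keys k, counts).  Missing values are dropped with a log."""
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    v = np.asarray(values, dtype=float)
    n_missing = int(np.isnan(v).sum())
    if n_missing:
        logger.warning("histogram: %d missing value(s) dropped", n_missing)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return [], {}
    k = np.floor((v - anchor) / binwidth).astype(int)
    ks = list(range(int(k.min()), int(k.max()) + 1))
    counts = {kk: int((k == kk).sum()) for kk in ks}
    return ks, counts


def render_histogram(values, binwidth: float, anchor: float = 0.0,
                     selected=None, bar_width: float = 20.0,
                     max_height: float = 100.0) -> Scene:
    """Histogram with user-set binwidth; a value on a bin edge falls in the
    right (higher) bin.  Sub-bars show the selected fraction per bin."""
    ks, counts = histogram_counts(values, binwidth, anchor)
    if not ks:
        logger.warning("histogram: no observed values, empty scene")
        return Scene(width=0.0, height=max_height)
    bars = {k: counts[k] for k in ks}
    sel_bars = {}
    if selected is not None:
        v = np.asarray(values, dtype=float)
        mask = np.zeros(len(v), dtype=bool)
        mask[list(selected)] = True
        vs = v[mask & ~np.isnan(v)]
        if vs.size:
            kk = np.floor((vs - anchor) / binwidth).astype(int)
            sel_bars = {int(k): int((kk == k).sum()) for k in np.unique(kk)}
    scene = render_barchart(bars, order="as-given", selected_counts=sel_bars,
                            bar_width=bar_width, max_height=max_height)
    # rewrite provenance from class labels to bin keys
    out = Scene(scene.width, scene.height)
    for p in scene.primitives:
        out.add(p.kind, p.geometry, p.color,
                p.provenance.replace("class:", "bin:"), p.highlighted)
    return out


def render_eventchart(times, statuses, subject_ids: Sequence[str],
                      group: Mapping | Sequence | None = None,
                      selection: Selection | None = None,
                      row_height: float = 10.0, width: float = 200.0) -> Scene:
    """Per-subject time-to-event chart.

    One horizontal line per subject from 0 to the observed time; a small
    terminal tick marks an observed event, its absence marks a censored
    observation.  ``group`` (a per-subject categorical) makes the lines of
    each class contiguous, classes separated by a blank row, in order of
    first appearance.
    """
    sel = _sel(selection)
    t = np.asarray(times, dtype=float)
    ev = np.asarray(statuses, dtype=bool)
    with np.errstate(invalid="ignore"):
        if np.any(t < 0):
            raise ValueError("event times must be >= 0")
    if group is not None and not isinstance(group, Mapping):
        group = dict(zip(subject_ids, group))
    order: list[int] = list(range(len(subject_ids)))
    blocks: list[list[int]] = [order]
    if group is not None:
        levels: list = []
        for sid in subject_ids:
            g = group.get(sid)
            if g not in levels:
                levels.append(g)
        blocks = [[i for i, sid in enumerate(subject_ids) if group.get(sid) == lv]
                  for lv in levels]
    tmax = float(np.nanmax(t)) if np.isfinite(t).any() else 1.0
    tmax = tmax or 1.0
    n_rows = sum(len(b) for b in blocks) + max(len(blocks) - 1, 0)
    scene = Scene(width=width, height=row_height * n_rows)
    row = 0
    for b, block in enumerate(blocks):
        for i in block:
            if not np.isfinite(t[i]):
                row += 1
                continue
            y = (row + 0.5) * row_height
            x = width * t[i] / tmax
            hl = subject_ids[i] in sel.samples
            scene.add("line", (0.0, y, x, y), "#333333",
                      provenance=subject_ids[i], highlighted=hl)
            if ev[i]:
                scene.add("tick", (x, y - row_height * 0.3, x, y + row_height * 0.3),
                          "#333333", provenance=subject_ids[i], highlighted=hl)
            row += 1
        if b < len(blocks) - 1:
            row += 1  # blank separator row between groups
    return scene


def render_correlation_matrix(matrix: FeatureMatrix, axis: str = "rows",
                              method: str = "pearson", cell: float = CELL) -> Scene:
    """Heatmap of the item–item correlation matrix on a fixed [−1, 1]
    diverging scale; the diagonal is exactly the +1 color.  Zero-variance
    items get missing-colored rows/columns."""
    frame = matrix.to_frame()
    if axis == "rows":
        frame = frame.T  # pandas correlates columns
        ids = matrix.row_ids
    elif axis == "columns":
        ids = matrix.col_ids
    else:
        raise ValueError("axis must be 'rows' or 'columns'")
    corr = frame.corr(method=method, min_periods=2).to_numpy()
    np.fill_diagonal(corr, 1.0)
    scale = DivergingScale(-1.0, 1.0)
    n = len(ids)
    scene = Scene(width=cell * n, height=cell * n)
    for i in range(n):
        for j in range(n):
            scene.add("rect", (j * cell, i * cell, cell, cell),
                      scale(corr[i, j]), provenance=f"{ids[i]}|{ids[j]}")
    return scene


def render_confusion(cm: ConfusionMatrix, cell: float = 30.0) -> Scene:
    """Agreement plot: one rect per non-zero cell, area ∝ count, rows and
    columns in the diagonal-maximizing sorted order (identity if unsorted)."""
    counts = cm.counts
    rp = cm.row_perm if cm.row_perm is not None else np.arange(counts.shape[0])
    cp = cm.col_perm if cm.col_perm is not None else np.arange(counts.shape[1])
    P = counts[np.ix_(rp, cp)]
    peak = counts.max() or 1
    r, c = P.shape
    scene = Scene(width=cell * c, height=cell * r)
    for i in range(r):
        for j in range(c):
            if P[i, j] == 0:
                continue
            side = cell * np.sqrt(P[i, j] / peak)
            x = j * cell + (cell - side) / 2.0
            y = i * cell + (cell - side) / 2.0
            scene.add("rect", (x, y, side, side), "#4e79a7",
                      provenance=f"{cm.row_labels[rp[i]]}|{cm.col_labels[cp[j]]}")
    return scene
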