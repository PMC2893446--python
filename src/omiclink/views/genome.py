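"""Copy-number aberration profiles and the chromosome browser.

Per-marker gain and loss frequencies across samples are computed from the
state matrix and drawn as barcharts along the chromosome axis: gains
upward, losses downward, positions scaled linearly to base pairs.  A
genome overview stacks one axis per chromosome; the single-chromosome
mode enlarges one axis and adds a cytoband track when a banding table is
available.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..datamodel import GenomicFeature, Selection, StateMatrix, normalize_chromosome
from .scene import Scene

logger = logging.getLogger(__name__)

__all__ = ["aberration_frequencies", "render_chromosome_browser"]

GAIN_COLOR = "#b2182b"
LOSS_COLOR = "#2166ac"

#: cytogenetic stain -> grey level for the band track
_STAIN_COLORS = {
    "gneg": "#ffffff", "gpos25": "#c8c8c8", "gpos50": "#969696",
    "gpos75": "#646464", "gpos100": "#323232", "acen": "#b2182b",
    "gvar": "#dcdcdc", "stalk": "#6464a0",
}


def aberration_frequencies(states: StateMatrix,
                           markers: Sequence[GenomicFeature],
                           chromosome: str) -> pd.DataFrame:
    """Per-marker gain/loss fractions along one chromosome.

    For each marker located on ``chromosome`` (sorted by start position),
    the gain fraction is the share of samples with state +1 among samples
    with a non-missing state; loss analogously, so gain + loss + normal
    fractions sum to 1 over the observed samples.  Markers with no
    observed state are omitted with a logged count; a chromosome without
    markers yields an empty frame.

    Returns a frame with columns
    ``marker, chromosome, start, end, gain, loss, n_observed``.
    """
    chromosome = normalize_chromosome(chromosome)
    row_index = {m: i for i, m in enumerate(states.row_ids)}
    located = sorted(
        (f for f in markers if f.chromosome == chromosome and f.id in row_index),
        key=lambda f: (f.start, f.id))
    records = []
    n_unobserved = 0
    for f in located:
        row = states.values[row_index[f.id]]
        obs = ~np.isnan(row)
        n = int(obs.sum())
        if n == 0:
            n_unobserved += 1
            continue
        records.append({
            "marker": f.id, "chromosome": chromosome,
            "start": f.start, "end": f.end,
            "gain": float((row[obs] == 1).sum() / n),
            "loss": float((row[obs] == -1).sum() / n),
            "n_observed": n,
        })
    if n_unobserved:
        logger.warning("aberration_frequencies(%s): %d marker(s) with no observed "
                       "state omitted", chromosome, n_unobserved)
    cols = ["marker", "chromosome", "start", "end", "gain", "loss", "n_observed"]
    return pd.DataFrame.from_records(records, columns=cols)


def _axis_bars(scene: Scene, freqs: pd.DataFrame, length: int, x0: float,
               y_axis: float, axis_width: float, bar_height: float,
               selection: Selection) -> None:
    scene.add("line", (x0, y_axis, x0 + axis_width, y_axis), "#333333")
    for rec in freqs.itertuples(index=False):
        x = x0 + axis_width * ((rec.start + rec.end) / 2.0) / length
        hl = rec.marker in selection.markers
        if rec.gain > 0:
            scene.add("rect", (x - 1.0, y_axis - bar_height * rec.gain,
                               2.0, bar_height * rec.gain), GAIN_COLOR,
                      provenance=rec.marker, highlighted=hl)
        if rec.loss > 0:
            scene.add("rect", (x - 1.0, y_axis, 2.0, bar_height * rec.loss),
                      LOSS_COLOR, provenance=rec.marker, highlighted=hl)


def render_chromosome_browser(frequencies: Mapping[str, pd.DataFrame],
                              chromosome_lengths: Mapping[str, int],
                              cytobands: Sequence[Mapping] | None = None,
                              mode: str = "genome-overview",
                              chromosome: str | None = None,
                              selection: Selection | None = None) -> Scene:
    """Draw gain/loss frequency profiles along chromosome axes.

    ``frequencies`` maps chromosome name to the output of
    :func:`aberration_frequencies`; ``chromosome_lengths`` fixes the
    base-pair scale (and the chromosome display order).  In
    ``genome-overview`` mode every chromosome gets its own axis; in
    ``single-chromosome`` mode one chromosome is enlarged and a cytoband
    track (records with name/chromosome/start/end/stain) is added beneath
    the axis when provided, or skipped with a log when absent.
    """
    selection = selection if selection is not None else Selection()
    if mode == "genome-overview":
        chroms = [normalize_chromosome(c) for c in chromosome_lengths]
        row_h, axis_w, bar_h = 60.0, 300.0, 20.0
        scene = Scene(width=axis_w + 40.0, height=row_h * len(chroms))
        for k, chrom in enumerate(chroms):
            y_axis = k * row_h + row_h / 2.0
            scene.add("text", (2.0, y_axis, chrom), "#333333")
            freqs = frequencies.get(chrom)
            if freqs is None or len(freqs) == 0:
                freqs = pd.DataFrame(columns=["marker", "chromosome", "start",
                                              "end", "gain", "loss", "n_observed"])
            _axis_bars(scene, freqs, int(chromosome_lengths[chrom]), 30.0,
                       y_axis, axis_w, bar_h, selection)
        return scene
    if mode != "single-chromosome":
        raise ValueError("mode must be 'genome-overview' or 'single-chromosome'")
    if chromosome is None:
        raise ValueError("single-chromosome mode requires a chromosome")
    chrom = normalize_chromosome(chromosome)
    axis_w, bar_h = 600.0, 80.0
    scene = Scene(width=axis_w + 40.0, height=3 * bar_h)
    y_axis = bar_h * 1.5
    freqs = frequencies.get(chrom)
    if freqs is None:
        freqs = pd.DataFrame(columns=["marker", "chromosome", "start",
                                      "end", "gain", "loss", "n_observed"])
    length = int(chromosome_lengths[chrom])
    _axis_bars(scene, freqs, length, 20.0, y_axis, axis_w, bar_h, selection)
    if cytobands is None:
        logger.warning("chromosome browser: no cytoband table, band track skipped")
    else:
        for band in cytobands:
            if normalize_chromosome(band["chromosome"]) != chrom:
                continue
            x = 20.0 + axis_w * (band["start"] - 1) / length
            w = axis_w * (band["end"] - band["start"] + 1) / length
            scene.add("rect", (x, y_axis + bar_h + 10.0, w, 12.0),
                      _STAIN_COLORS.get(band.get("stain", "gneg"), "#ffffff"),
                      provenance=f"band:{band['name']}")
    return scene
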