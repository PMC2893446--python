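"""The linking engine: coordinate mapping and selection propagation.

Copy-number markers (array CGH clones, SNPs) and genes live on the same
genome, so a marker is *linked* to every gene whose interval it overlaps
on the same chromosome (closed 1-based intervals, one shared base
suffices; the relation is many-to-many — a clone spanning two genes links
both).  Samples are linked across datasets by shared identifiers, and a
derived result links to its member objects.  Propagating a selection
closes it under all three relations, which is what makes a brushing
gesture in one view light up every other view.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .datamodel import GenomicFeature, Registry, Selection

logger = logging.getLogger(__name__)

__all__ = ["LinkMap", "build_linkmap", "propagate_selection",
           "assign_class_colors", "DEFAULT_PALETTE"]


@dataclass
class LinkMap:
    """Bidirectional many-to-many marker ↔ gene relation."""

    marker_to_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    gene_to_markers: dict[str, frozenset[str]] = field(default_factory=dict)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted((m, g) for m, gs in self.marker_to_genes.items() for g in gs)

    def genes_for(self, markers: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for m in markers:
            out |= self.marker_to_genes.get(m, frozenset())
        return frozenset(out)

    def markers_for(self, genes: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for g in genes:
            out |= self.gene_to_markers.get(g, frozenset())
        return frozenset(out)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("marker_id\tgene_id\n")
            for m, g in self.pairs():
                fh.write(f"{m}\t{g}\n")


def build_linkmap(markers: Sequence[GenomicFeature],
                  genes: Sequence[GenomicFeature]) -> LinkMap:
    """Link every marker to the genes it overlaps on the same chromosome.

    Intervals are closed and 1-based; overlap of at least one base links
    the pair.  Empty inputs give an empty map.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # interval tree is half-open; +1 makes the closed endpoint inclusive
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end + 1, g.id)
    m2g: dict[str, set[str]] = {}
    g2m: dict[str, set[str]] = {}
    for m in markers:
        tree = trees.get(m.chromosome)
        if tree is None:
            continue
        for hit in tree.overlap(m.start, m.end + 1):
            m2g.setdefault(m.id, set()).add(hit.data)
            g2m.setdefault(hit.data, set()).add(m.id)
    return LinkMap({m: frozenset(v) for m, v in m2g.items()},
                   {g: frozenset(v) for g, v in g2m.items()})


def _result_selection(registry: Registry, result_id: str) -> Selection:
    """The objects a selected (sub-)result contributes."""
    groups = registry.members_of(result_id)
    return Selection.of(genes=groups.get("gene", ()),
                        samples=groups.get("sample", ()),
                        markers=groups.get("marker", ()))


def propagate_selection(selection: Selection, registry: Registry,
                        linkmap: LinkMap | None = None) -> Selection:
    """Close a selection under all linking relations.

    Closure rules, applied to a fixed point:

    * a selected result object selects its members (a bicluster selects
      its genes and samples);
    * a selected gene selects every linked marker and vice versa.

    Samples need no rule: identifiers are shared across datasets, so a
    selected sample is already "the same object" everywhere.  The result
    is monotone (⊇ input) and idempotent.  Unknown identifiers raise.
    """
    for ids, cls in ((selection.genes, "gene"), (selection.samples, "sample"),
                     (selection.markers, "marker"), (selection.results, "result")):
        universe = registry.universe(cls)
        unknown = set(ids) - universe
        if unknown:
            raise KeyError(f"unknown {cls} identifier(s): {sorted(unknown)[:5]}")
    current = selection
    while True:
        nxt = current
        for rname in current.results:
            nxt = nxt | _result_selection(registry, rname)
        if linkmap is not None:
            nxt = nxt | Selection.of(markers=linkmap.markers_for(current.genes))
            nxt = nxt | Selection.of(genes=linkmap.genes_for(current.markers))
        if nxt.size() == current.size():
            return nxt
        current = nxt


#: 10 colour-blind-aware hex colors (Tableau 10)
DEFAULT_PALETTE = (
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
)


def assign_class_colors(levels: Sequence, palette: Sequence[str] = DEFAULT_PALETTE) -> dict:
    """Stable class → color mapping for a categorical variable.

    Classes are colored in order of first appearance; the same input
    always yields the same mapping, so every view shares one legend.
    With more classes than palette entries the palette cycles, with a
    logged warning.
    """
    classes: list = []
    for v in levels:
        if v not in classes and v is not None:
            classes.append(v)
    if len(classes) > len(palette):
        logger.warning("assign_class_colors: %d classes exceed the %d-color palette; "
                       "colors will repeat", len(classes), len(palette))
    cycle = itertools.cycle(palette)
    return {cls: col for cls, col in zip(classes, cycle)}
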