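"""Seeded synthetic integrated study with known planted structure.

The generator emulates the shape of a translational leukemia study: a
preprocessed expression matrix (genes × samples, log-ratio scale), a
copy-number state matrix from array CGH / SNP calls (markers × samples,
−1/0/+1), genomic positions for genes and markers on two synthetic
chromosomes, and a clinical table with a categorical subgroup, a
continuous covariate and censored survival.  Patient subgroups carry
distinct up-regulated gene blocks and distinct copy-number segments —
the situation where expression subgroups reflect underlying secondary
aberrations — plus an additive (shifted-pattern) bicluster cutting
across part of the cohort.

Every planted assignment is recorded in a ground-truth record, so the
generator doubles as the oracle for recovery experiments, and the same
seed reproduces byte-identical serialized output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datamodel import (
    ClinicalTable,
    ClinicalVariable,
    FeatureMatrix,
    GenomicFeature,
    StateMatrix,
)
from . import ingest

__all__ = ["GeneBlock", "Group", "PlantedBicluster", "Segment", "StudyDesign",
           "SimulatedStudy", "default_design", "simulate_study",
           "planted_shift_matrix"]


@dataclass(frozen=True)
class GeneBlock:
    """A contiguous block of genes regulated in one group; effect in units
    of the per-gene noise standard deviation (negative = down)."""

    first_gene: int
    n_genes: int
    effect: float


@dataclass(frozen=True)
class Group:
    """A patient subgroup with its expression signature and survival."""

    name: str
    size: int
    blocks: tuple[GeneBlock, ...]
    survival_rate: float  # exponential event rate, 1/month


@dataclass(frozen=True)
class PlantedBicluster:
    """Additive shifted-pattern block: cell (i, j) = row offset + column
    offset + N(0, noise_sd), replacing the background.

    Offsets are drawn uniformly from ±``offset_spread``; keeping the
    spread below the background standard deviation makes the block a
    coherent structure rather than a magnitude outlier, the regime
    mean-squared-residue biclustering is designed for.
    """

    first_gene: int
    n_genes: int
    first_sample: int
    n_samples: int
    noise_sd: float = 0.1
    offset_spread: float = 0.5


@dataclass(frozen=True)
class Segment:
    """A copy-number aberration: ``state`` (+1/−1) applied to all markers
    in [start, end] for a per-group fraction of carrier samples (carriers
    are the first ``round(fraction · size)`` samples of each group, so
    planted frequencies are exact)."""

    chromosome: str
    start: int
    end: int
    state: int
    carrier_fraction: dict[str, float]


@dataclass(frozen=True)
class StudyDesign:
    n_genes: int = 500
    n_markers: int = 300
    groups: tuple[Group, ...] = (
        Group("inv16", 30, (GeneBlock(0, 50, 2.0),), 1 / 60.0),
        Group("t8_21", 30, (GeneBlock(50, 50, 2.0),), 1 / 20.0),
    )
    bicluster: PlantedBicluster | None = PlantedBicluster(150, 20, 5, 15)
    segments: tuple[Segment, ...] = (
        Segment("1", 50_000_001, 80_000_000, +1, {"inv16": 1.0, "t8_21": 0.0}),
        Segment("2", 20_000_001, 60_000_000, -1, {"inv16": 0.0, "t8_21": 0.5}),
    )
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 200_000_000, "2": 150_000_000})
    censoring_rate: float = 0.2
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(g.size for g in self.groups)

    def validate(self) -> None:
        for g in self.groups:
            for b in g.blocks:
                if b.first_gene + b.n_genes > self.n_genes:
                    raise ValueError(f"gene block of {g.name} exceeds n_genes")
        if self.bicluster is not None:
            b = self.bicluster
            if (b.first_gene + b.n_genes > self.n_genes
                    or b.first_sample + b.n_samples > self.n_samples):
                raise ValueError("planted bicluster exceeds matrix dimensions")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")


def default_design(seed: int = 0) -> StudyDesign:
    return StudyDesign(seed=seed)


@dataclass
class SimulatedStudy:
    design: StudyDesign
    expression: FeatureMatrix
    states: StateMatrix
    gene_features: list[GenomicFeature]
    marker_features: list[GenomicFeature]
    clinical: ClinicalTable
    truth: dict

    def write(self, directory) -> dict[str, str]:
        """Write every table in the tab-delimited dialect the readers
        consume, plus the ground truth; returns the file map."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        ingest.write_expression(self.expression, d / "expression.tsv")
        ingest.write_states(self.states, d / "states.tsv")
        ingest.write_features(self.gene_features, d / "genes.tsv")
        ingest.write_features(self.marker_features, d / "markers.tsv")
        ingest.write_clinical(self.clinical, d / "clinical.tsv")
        (d / "ground_truth.json").write_text(
            json.dumps(self.truth, sort_keys=True, indent=1) + "\n")
        cfg = {
            "expression.id_column": "gene_id",
            "states.id_column": "marker_id",
            "features.id_column": "id",
            "features.chromosome_column": "chromosome",
            "features.start_column": "start",
            "features.end_column": "end",
            "clinical.id_column": "sample_id",
            "clinical.types": "group:categorical,age:continuous,os:time_to_event",
            "chromosome_lengths": ",".join(
                f"{c}:{l}" for c, l in self.design.chromosome_lengths.items()),
        }
        ingest.write_config(cfg, d / "config.txt")
        return {name: str(d / f"{name}.tsv")
                for name in ("expression", "states", "genes", "markers", "clinical")}


def _place_features(rng, prefix: str, count: int, lengths: dict[str, int],
                    point: bool) -> list[GenomicFeature]:
    """Spread features over the chromosomes proportionally to length,
    uniform positions, sorted by (chromosome, start)."""
    total = sum(lengths.values())
    feats: list[GenomicFeature] = []
    k = 0
    chroms = list(lengths)
    per = [int(round(count * lengths[c] / total)) for c in chroms]
    per[-1] = count - sum(per[:-1])
    for chrom, n in zip(chroms, per):
        starts = np.sort(rng.integers(1, lengths[chrom] - 1_000_000, size=n))
        for s in starts:
            if point:
                start = end = int(s)
            else:
                start = int(s)
                end = start + int(rng.integers(10_000, 200_000))
            feats.append(GenomicFeature(f"{prefix}{k:04d}", chrom, start, end))
            k += 1
    return feats


def simulate_study(design: StudyDesign | None = None) -> SimulatedStudy:
    """Generate the full integrated study from a design (see module docs).

    Deterministic given ``design.seed``; the returned ``truth`` dict
    records every planted assignment.
    """
    design = design if design is not None else default_design()
    design.validate()
    rng = np.random.default_rng(design.seed)
    n, p, m = design.n_samples, design.n_genes, design.n_markers
    gene_ids = [f"g{i:04d}" for i in range(p)]
    sample_ids = [f"s{j:03d}" for j in range(n)]
    marker_ids = [f"m{i:04d}" for i in range(m)]

    # -- group structure ----------------------------------------------------
    group_of: list[str] = []
    for g in design.groups:
        group_of.extend([g.name] * g.size)
    group_cols = {g.name: [j for j, lab in enumerate(group_of) if lab == g.name]
                  for g in design.groups}

    # -- expression: unit gaussian background + block effects ---------------
    X = rng.normal(0.0, 1.0, size=(p, n))
    for g in design.groups:
        for b in g.blocks:
            rows = slice(b.first_gene, b.first_gene + b.n_genes)
            X[rows, group_cols[g.name]] += b.effect
    truth_bicluster = None
    if design.bicluster is not None:
        b = design.bicluster
        rows = np.arange(b.first_gene, b.first_gene + b.n_genes)
        cols = np.arange(b.first_sample, b.first_sample + b.n_samples)
        row_off = rng.uniform(-b.offset_spread, b.offset_spread, size=b.n_genes)
        col_off = rng.uniform(-b.offset_spread, b.offset_spread, size=b.n_samples)
        X[np.ix_(rows, cols)] = (row_off[:, None] + col_off[None, :]
                                 + rng.normal(0.0, b.noise_sd, (b.n_genes, b.n_samples)))
        truth_bicluster = {"genes": [gene_ids[i] for i in rows],
                           "samples": [sample_ids[j] for j in cols],
                           "noise_sd": b.noise_sd}
    expression = FeatureMatrix(X, gene_ids, sample_ids)

    # -- genomic positions ---------------------------------------------------
    gene_features = _place_features(rng, "g_pos_", p, design.chromosome_lengths, False)
    gene_features = [GenomicFeature(gid, f.chromosome, f.start, f.end)
                     for gid, f in zip(gene_ids, gene_features)]
    marker_features = _place_features(rng, "m_pos_", m, design.chromosome_lengths, True)
    marker_features = [GenomicFeature(mid, f.chromosome, f.start, f.end)
                       for mid, f in zip(marker_ids, marker_features)]

    # -- copy-number states --------------------------------------------------
    S = np.zeros((m, n))
    truth_segments = []
    for seg in design.segments:
        seg_markers = [i for i, f in enumerate(marker_features)
                       if f.chromosome == seg.chromosome
                       and f.start >= seg.start and f.end <= seg.end]
        carriers: list[int] = []
        for g in design.groups:
            frac = seg.carrier_fraction.get(g.name, 0.0)
            k = int(round(frac * g.size))
            carriers.extend(group_cols[g.name][:k])
        S[np.ix_(seg_markers, carriers)] = seg.state
        truth_segments.append({
            "chromosome": seg.chromosome, "start": seg.start, "end": seg.end,
            "state": seg.state,
            "carrier_fraction": dict(seg.carrier_fraction),
            "overall_fraction": len(carriers) / n,
            "markers": [marker_ids[i] for i in seg_markers],
            "carriers": [sample_ids[j] for j in carriers],
        })
    states = StateMatrix(S, marker_ids, sample_ids)

    # -- clinical ------------------------------------------------------------
    age = np.round(rng.normal(55.0, 10.0, size=n), 1)
    event_time = np.empty(n)
    for g in design.groups:
        cols = group_cols[g.name]
        event_time[cols] = rng.exponential(1.0 / g.survival_rate, size=len(cols))
    censored = rng.random(n) < design.censoring_rate
    obs_time = np.where(censored, rng.random(n) * event_time, event_time)
    obs_time = np.round(obs_time, 2)
    clinical = ClinicalTable(sample_ids, {
        "group": ClinicalVariable("categorical", np.array(group_of, dtype=object)),
        "age": ClinicalVariable("continuous", age),
        "os": ClinicalVariable("time_to_event", obs_time, ~censored),
    })

    truth = {
        "seed": design.seed,
        "groups": {g.name: {"samples": [sample_ids[j] for j in group_cols[g.name]],
                            "survival_rate": g.survival_rate,
                            "blocks": [asdict(b) for b in g.blocks]}
                   for g in design.groups},
        "group_of": dict(zip(sample_ids, group_of)),
        "bicluster": truth_bicluster,
        "segments": truth_segments,
        "censoring_rate": design.censoring_rate,
        "n_censored": int(censored.sum()),
    }
    return SimulatedStudy(design, expression, states, gene_features,
                          marker_features, clinical, truth)


def planted_shift_matrix(n_rows: int = 30, n_cols: int = 20,
                         block_rows: int = 15, block_cols: int = 10,
                         noise_sd: float = 0.1, offset_spread: float = 0.5,
                         seed: int = 0):
    """Small matrix with one planted shifted-pattern (additive) bicluster
    in unit gaussian background — the standard recovery benchmark for
    mean-squared-residue biclustering.

    Row/column offsets are uniform on ±``offset_spread`` (kept below the
    background sd so the block is coherent, not a magnitude outlier).
    Returns ``(matrix, row_indices, col_indices)`` of the planted block
    (placed in the top-left corner; recovery metrics are permutation-free).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, size=(n_rows, n_cols))
    rows = np.arange(block_rows)
    cols = np.arange(block_cols)
    row_off = rng.uniform(-offset_spread, offset_spread, size=block_rows)
    col_off = rng.uniform(-offset_spread, offset_spread, size=block_cols)
    X[np.ix_(rows, cols)] = (row_off[:, None] + col_off[None, :]
                             + rng.normal(0.0, noise_sd, (block_rows, block_cols)))
    return X, rows, cols
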