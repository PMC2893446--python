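"""Typed containers for the integrated study and the data-manager registry.

The library organizes a study into a small set of related object classes —
genes, samples, copy-number markers (array CGH clones / SNPs), chromosomes —
plus derived results (dendrograms, partitions, biclusters, seriations).
A :class:`Registry` holds raw datasets and derived results as addressable,
linkable objects sharing one identifier universe, which is what makes
selection propagation across views possible.

Conventions
-----------
* Chromosome names are normalized to ``"1"``–``"22"``, ``"X"``, ``"Y"``
  (a leading ``chr`` is stripped, case-insensitively).
* Genomic coordinates are 1-based, closed intervals; a point feature
  (a SNP) has ``start == end``.
* Missing values are ``NaN`` in both matrix types; each operation states
  its own missing-value policy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "StateMatrix",
    "GenomicFeature",
    "ClinicalVariable",
    "ClinicalTable",
    "Registry",
    "Selection",
    "normalize_chromosome",
]

_CHROM_RE = re.compile(r"^(?:chr)?(\d{1,2}|[XYxy])$", re.IGNORECASE)

#: object classes known to the registry
OBJECT_CLASSES = ("gene", "sample", "marker", "chromosome", "result")


def normalize_chromosome(name: str) -> str:
    """Normalize a chromosome name to ``"1"``–``"22"``, ``"X"`` or ``"Y"``.

    A leading ``chr`` prefix is stripped case-insensitively; ``x``/``y``
    are upper-cased.  Raises :class:`ValueError` for anything else.
    """
    m = _CHROM_RE.match(str(name).strip())
    if not m:
        raise ValueError(f"unrecognized chromosome name: {name!r}")
    core = m.group(1).upper()
    if core.isdigit() and not 1 <= int(core) <= 22:
        raise ValueError(f"autosome number out of range: {name!r}")
    return core


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} identifiers: {dup[:5]}")
    return ids


@dataclass
class FeatureMatrix:
    """Real-valued expression matrix, rows = genes, columns = samples.

    ``values`` is a dense float array; missing entries are ``NaN`` and are
    preserved through any reordering.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.row_ids = _check_ids(self.row_ids, "row")
        self.col_ids = _check_ids(self.col_ids, "column")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"({len(self.row_ids)}, {len(self.col_ids)}) identifiers"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns))

    def reorder(self, row_order: Sequence[int] | None = None,
                col_order: Sequence[int] | None = None) -> "FeatureMatrix":
        """Return a copy with rows/columns permuted (missingness preserved)."""
        r = np.arange(len(self.row_ids)) if row_order is None else np.asarray(row_order)
        c = np.arange(len(self.col_ids)) if col_order is None else np.asarray(col_order)
        return type(self)(
            self.values[np.ix_(r, c)],
            [self.row_ids[i] for i in r],
            [self.col_ids[j] for j in c],
        )


class StateMatrix(FeatureMatrix):
    """Copy-number state matrix, rows = markers, columns = samples.

    Entries are −1 (loss), 0 (normal), +1 (gain) or ``NaN`` (missing).
    Sample identifiers live in the same namespace as expression columns,
    which is what links the two data types.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values
        ok = np.isnan(vals) | np.isin(vals, (-1.0, 0.0, 1.0))
        if not ok.all():
            bad = np.unique(vals[~ok])
            raise ValueError(f"state entries must be in {{-1, 0, +1}}; found {bad[:5]}")


@dataclass(frozen=True)
class GenomicFeature:
    """A located object: gene, array CGH clone or SNP.

    Coordinates are 1-based closed base-pair positions; ``start == end``
    for a point feature.
    """

    id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.id}: coordinates must be positive (1-based)")
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")

    @property
    def is_point(self) -> bool:
        return self.start == self.end


VARIABLE_KINDS = ("categorical", "continuous", "time_to_event")


@dataclass
class ClinicalVariable:
    """One typed clinical column.

    kind
        ``categorical`` | ``continuous`` | ``time_to_event``.  The tag is
        explicit — never inferred silently at use time.
    values
        per-sample values; category labels (object), floats, or event/
        censoring times (float, ≥ 0) depending on kind.
    event
        for ``time_to_event`` only: boolean per sample, True where the
        event was observed, False where the observation is censored.
    """

    kind: str
    values: np.ndarray
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "continuous":
            self.values = np.asarray(self.values, dtype=float)
        else:
            self.values = np.asarray(self.values)
        if self.kind == "time_to_event":
            if self.event is None:
                raise ValueError("time_to_event variable needs an event status array")
            self.values = np.asarray(self.values, dtype=float)
            self.event = np.asarray(self.event, dtype=bool)
            with np.errstate(invalid="ignore"):
                if np.any(self.values < 0):
                    raise ValueError("event times must be >= 0")
            if self.event.shape != self.values.shape:
                raise ValueError("time and status arrays differ in length")

    def levels(self) -> list:
        """Observed levels of a categorical variable, in order of appearance."""
        if self.kind != "categorical":
            raise ValueError("levels() is only defined for categorical variables")
        seen: dict = {}
        for v in self.values:
            if not (isinstance(v, float) and np.isnan(v)) and v not in seen:
                seen[v] = None
        return list(seen)


@dataclass
class ClinicalTable:
    """Per-sample clinical variables with explicit type tags (one row per sample)."""

    sample_ids: list[str]
    variables: dict[str, ClinicalVariable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name, var in self.variables.items():
            if len(var.values) != n:
                raise ValueError(f"variable {name!r} has {len(var.values)} values for {n} samples")

    def __getitem__(self, name: str) -> ClinicalVariable:
        return self.variables[name]


# --------------------------------------------------------------------------
# registry ("data manager")

#: dataset kinds -> (row object class, column object class or None)
_DATASET_CLASSES = {
    "expression": ("gene", "sample"),
    "states": ("marker", "sample"),
    "clinical": ("sample", None),
}


def _dataset_objects(dataset, kind: str | None):
    """Yield (object_class, ids) pairs contributed by a raw dataset."""
    if isinstance(dataset, StateMatrix):
        yield "marker", list(dataset.row_ids)
        yield "sample", list(dataset.col_ids)
    elif isinstance(dataset, FeatureMatrix):
        yield "gene", list(dataset.row_ids)
        yield "sample", list(dataset.col_ids)
    elif isinstance(dataset, ClinicalTable):
        yield "sample", list(dataset.sample_ids)
    elif isinstance(dataset, (list, tuple)) and all(isinstance(f, GenomicFeature) for f in dataset):
        if kind not in ("gene", "marker"):
            raise ValueError("registering features requires kind='gene' or kind='marker'")
        yield kind, [f.id for f in dataset]
        yield "chromosome", sorted({f.chromosome for f in dataset})
    else:
        raise TypeError(f"unsupported dataset type {type(dataset).__name__}")


class Registry:
    """Data manager: named raw datasets plus derived results in a tree.

    Every identifier resolves to exactly one object class; this is asserted
    on every mutation, so a gene id can never collide with a sample id.
    Derived results (dendrograms, partitions, biclusters, seriations) hang
    under the dataset they were computed from and may reference only
    identifiers present in that parent.
    """

    def __init__(self) -> None:
        self.datasets: dict[str, object] = {}
        self.results: dict[str, object] = {}
        self._children: dict[str, list[str]] = {}
        self._parent: dict[str, str] = {}
        self._classes: dict[str, str] = {}  # id -> object class
        self._dataset_ids: dict[str, dict[str, set[str]]] = {}

    # -- identifier universe -------------------------------------------------
    def universe(self, object_class: str) -> set[str]:
        """All known identifiers of one class."""
        if object_class not in OBJECT_CLASSES:
            raise ValueError(f"unknown object class {object_class!r}")
        return {i for i, c in self._classes.items() if c == object_class}

    def class_of(self, identifier: str) -> str:
        try:
            return self._classes[identifier]
        except KeyError:
            raise KeyError(f"unknown identifier {identifier!r}") from None

    def _claim(self, ids: Iterable[str], object_class: str) -> None:
        for i in ids:
            existing = self._classes.get(i)
            if existing is not None and existing != object_class:
                raise ValueError(
                    f"identifier {i!r} already registered as {existing!r}, "
                    f"cannot re-register as {object_class!r}"
                )
        for i in ids:
            self._classes[i] = object_class

    # -- mutation -------------------------------------------------------------
    def register_dataset(self, name: str, dataset, kind: str | None = None) -> "Registry":
        """Add a raw dataset under ``name``; its objects enter the universe.

        ``kind`` disambiguates lists of :class:`GenomicFeature`
        (``"gene"`` or ``"marker"``).
        """
        if name in self.datasets or name in self.results:
            raise ValueError(f"name {name!r} already registered")
        contributions = list(_dataset_objects(dataset, kind))
        for cls, ids in contributions:
            self._claim(ids, cls)
        self.datasets[name] = dataset
        self._children[name] = []
        self._dataset_ids[name] = {}
        for cls, ids in contributions:
            self._dataset_ids[name].setdefault(cls, set()).update(ids)
        return self

    def register_result(self, name: str, parent: str, result) -> "Registry":
        """Attach a derived result under an existing dataset.

        The result must reference only identifiers present in the parent;
        a dangling identifier is an error.  ``result`` itself becomes a
        selectable object of class ``result``.
        """
        if parent not in self.datasets:
            raise KeyError(f"unknown parent dataset {parent!r}")
        if name in self.datasets or name in self.results:
            raise ValueError(f"name {name!r} already registered")
        parent_ids: set[str] = set()
        for ids in self._dataset_ids[parent].values():
            parent_ids |= ids
        dangling = set(_result_ids(result)) - parent_ids
        if dangling:
            raise ValueError(
                f"result {name!r} references identifiers absent from parent "
                f"{parent!r}: {sorted(dangling)[:5]}"
            )
        # sub-objects (single clusters of a partition, single biclusters of a
        # result set) are addressable as "<name>#<label>" / "<name>#<index>"
        subids = [f"{name}#{s}" for s in _result_subobjects(result)]
        self._claim([name, *subids], "result")
        self.results[name] = result
        self._children[parent].append(name)
        self._parent[name] = parent
        return self

    # -- retrieval ------------------------------------------------------------
    def get(self, name: str):
        if name in self.datasets:
            return self.datasets[name]
        if name in self.results:
            return self.results[name]
        raise KeyError(f"unknown name {name!r}")

    def children(self, dataset: str) -> list[str]:
        """Result names under a dataset, in insertion order."""
        return list(self._children[dataset])

    def parent_of(self, result: str) -> str:
        return self._parent[result]

    def tree(self) -> dict[str, list[str]]:
        """The data-manager tree: dataset name -> result names."""
        return {d: list(ch) for d, ch in self._children.items()}

    def members_of(self, result_id: str) -> dict[str, set[str]]:
        """Identifiers a (sub-)result selects, grouped by object class.

        Selecting a bicluster selects its genes (or markers) and samples;
        selecting a cluster ``"name#label"`` selects that cluster's
        members; selecting a whole result selects everything it covers.
        """
        name, _, sub = result_id.partition("#")
        if name not in self.results:
            raise KeyError(f"unknown result {result_id!r}")
        result = self.results[name]
        if sub:
            if isinstance(result, (list, tuple)):
                result = result[int(sub) - 1]
                ids = _result_ids(result)
            else:  # partition-like: one cluster's members
                labels = getattr(result, "labels")
                items = getattr(result, "item_ids")
                ids = {i for i, l in zip(items, labels) if int(l) == int(sub)}
        else:
            ids = _result_ids(result)
        out: dict[str, set[str]] = {}
        for i in ids:
            out.setdefault(self._classes.get(i, "?"), set()).add(i)
        return out


def _result_subobjects(result) -> list[str]:
    """Sub-object suffixes a result exposes for selection."""
    if isinstance(result, (list, tuple)):
        return [str(i + 1) for i in range(len(result))]
    labels = getattr(result, "labels", None)
    if labels is not None:  # partition-like
        return [str(int(l)) for l in sorted(set(int(x) for x in labels))]
    return []


def _result_ids(result) -> set[str]:
    """Identifiers a derived result references (ducks across result types)."""
    ids: set[str] = set()
    for attr in ("item_ids", "row_ids", "col_ids"):
        v = getattr(result, attr, None)
        if v is not None:
            ids.update(str(x) for x in v)
    if isinstance(result, (list, tuple)):
        for r in result:
            ids |= _result_ids(r)
    return ids


@dataclass(frozen=True)
class Selection:
    """Per-class sets of selected object identifiers.

    Immutable; propagation (see :mod:`omiclink.linkage`) returns enlarged
    copies.  All sets must be subsets of the registry's universe at use time.
    """

    genes: frozenset[str] = frozenset()
    samples: frozenset[str] = frozenset()
    markers: frozenset[str] = frozenset()
    results: frozenset[str] = frozenset()

    @classmethod
    def of(cls, genes: Iterable[str] = (), samples: Iterable[str] = (),
           markers: Iterable[str] = (), results: Iterable[str] = ()) -> "Selection":
        return cls(frozenset(genes), frozenset(samples),
                   frozenset(markers), frozenset(results))

    def __or__(self, other: "Selection") -> "Selection":
        return Selection(self.genes | other.genes, self.samples | other.samples,
                         self.markers | other.markers, self.results | other.results)

    def __le__(self, other: "Selection") -> bool:
        return (self.genes <= other.genes and self.samples <= other.samples
                and self.markers <= other.markers and self.results <= other.results)

    def is_empty(self) -> bool:
        return not (self.genes or self.samples or self.markers or self.results)

    def size(self) -> int:
        return len(self.genes) + len(self.samples) + len(self.markers) + len(self.results)
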