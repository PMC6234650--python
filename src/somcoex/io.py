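"""Count-matrix, metadata and annotation I/O plus the shared data model.

The pipeline starts at a gene-level read-count matrix (genes x samples,
TSV) accompanied by a sample sheet (substrate, growth point, replicate)
and an optional annotation table (gene -> namespaced labels such as CAZy
families or P450 clans).  All tables are tab-separated; gzip-compressed
files are read and written transparently.  Gene and sample order is
significant and preserved throughout -- downstream tie-breaking (e.g.
best-matching-unit selection) depends on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SomcoexError",
    "ValidationError",
    "ParseError",
    "CountMatrix",
    "SampleMetadata",
    "AnnotationTable",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
]

KNOWN_NAMESPACES = {"CAZy", "P450_clan", "housekeeping", "signalp", "unknown_function"}


class SomcoexError(Exception):
    """Base class for package errors."""


class ValidationError(SomcoexError):
    """An input object violates a structural invariant."""


class ParseError(SomcoexError):
    """A file could not be parsed; the message cites the offending cell."""


def _check_unique(ids: Iterable[str], kind: str) -> None:
    ids = list(ids)
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} ID: {x!r}")
        seen.add(x)


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples.

    ``counts`` is a DataFrame whose index holds gene IDs and whose columns
    hold sample IDs, both unique and order-preserving.  All entries are
    non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix needs >=1 gene and >=2 samples, got shape {df.shape}"
            )
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise ValidationError("counts must be integers")
        if (df.to_numpy() < 0).any():
            gene, sample = self._first_where(df.to_numpy() < 0)
            raise ValidationError(f"negative count at gene {gene!r}, sample {sample!r}")
        # canonical axis names so write/read round-trips are exact
        df.index.name = "gene_id"
        df.columns.name = None

    def _first_where(self, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(self.counts.index[i]), str(self.counts.columns[j])

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class SampleMetadata:
    """Per-sample design: substrate, growth point and replicate.

    A *condition* is a (substrate, growth_point) pair; growth points are
    ordered integers with the smallest one serving as the reference (GP1
    in the two-substrate, five-growth-point design).
    """

    table: pd.DataFrame  # index: sample_id; columns: substrate, growth_point, replicate

    def __post_init__(self) -> None:
        required = {"substrate", "growth_point", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        _check_unique(self.table.index, "sample")
        self.table = self.table.copy()
        try:
            self.table["growth_point"] = self.table["growth_point"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"growth_point not coercible to int: {exc}") from exc
        if len(self.growth_points) < 2:
            raise ValidationError("need at least 2 growth points")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def substrates(self) -> list[str]:
        return list(dict.fromkeys(self.table["substrate"]))

    @property
    def growth_points(self) -> list[int]:
        return sorted(self.table["growth_point"].unique())

    @property
    def reference_growth_point(self) -> int:
        return self.growth_points[0]

    @property
    def conditions(self) -> list[tuple[str, int]]:
        """All (substrate, growth point) pairs present, substrate-major order."""
        return [
            (s, g)
            for s in self.substrates
            for g in self.growth_points
            if self.samples_for(s, g)
        ]

    def samples_for(self, substrate: str, growth_point: int) -> list[str]:
        m = (self.table["substrate"] == substrate) & (
            self.table["growth_point"] == int(growth_point)
        )
        return list(self.table.index[m])

    def check_covers(self, counts: CountMatrix) -> None:
        """Every count-matrix sample must have metadata."""
        missing = [s for s in counts.sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        for s, g in self.conditions:
            if not self.samples_for(s, g):
                raise ValidationError(f"condition ({s}, GP{g}) has no replicates")


@dataclass
class AnnotationTable:
    """Gene -> set of (namespace, label) pairs.

    Annotated genes need not all appear in a count matrix; joining against
    a matrix warns about (but keeps) the extras.  Unknown namespaces are
    accepted with a warning so site-specific annotation sources pass
    through.
    """

    table: pd.DataFrame  # columns: gene_id, namespace, label
    _lookup: dict[str, set[tuple[str, str]]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"gene_id", "namespace", "label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
        if (self.table["label"].astype(str).str.len() == 0).any():
            raise ValidationError("empty annotation label")
        unknown = set(self.table["namespace"]) - KNOWN_NAMESPACES
        if unknown:
            warnings.warn(f"unknown annotation namespaces: {sorted(unknown)}", stacklevel=2)
        self._lookup = {}
        for g, ns, lab in self.table[["gene_id", "namespace", "label"]].itertuples(index=False):
            self._lookup.setdefault(str(g), set()).add((str(ns), str(lab)))

    def get(self, gene_id: str) -> set[tuple[str, str]]:
        return set(self._lookup.get(gene_id, set()))

    def genes_with(self, namespace: str, label: str | None = None) -> list[str]:
        m = self.table["namespace"] == namespace
        if label is not None:
            m &= self.table["label"] == label
        return list(dict.fromkeys(self.table.loc[m, "gene_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["gene_id"]))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV of integer read counts.

    Header row holds sample IDs, first column holds gene IDs.  Non-integer
    or negative entries raise :class:`ParseError` naming the cell.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")
    values = np.empty(raw.shape, dtype=np.int64)
    arr = raw.to_numpy()
    for j in range(raw.shape[1]):
        try:
            values[:, j] = np.asarray(arr[:, j], dtype=np.int64)
        except (TypeError, ValueError):
            for i in range(raw.shape[0]):
                try:
                    int(arr[i, j])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-integer count {arr[i, j]!r} at gene {raw.index[i]!r}, "
                        f"sample {raw.columns[j]!r}"
                    ) from None
            raise
    df = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return CountMatrix(df)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "substrate": str})
    if "sample_id" not in df.columns:
        raise ValidationError("metadata must have a sample_id column")
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(md: SampleMetadata, path: str | Path) -> None:
    md.table.to_csv(path, sep="\t", index_label="sample_id")


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return AnnotationTable(df)


def write_annotations(at: AnnotationTable, path: str | Path) -> None:
    at.table.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV of real-valued expression."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    values.to_csv(path, sep="\t", index_label="gene_id")
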