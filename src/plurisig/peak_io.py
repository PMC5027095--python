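"""Readers and writers for every on-disk format the pipeline touches.

Peak intervals come in as BED3+ / ENCODE narrowPeak / ENCODE broadPeak;
gene annotations, expression tables, dataset manifests and feature
matrices are plain TSV; gold-standard gene lists are one identifier per
line.  All genomic coordinates are BED-style 0-based half-open,
internally and on disk — no conversion ever happens inside the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Feature-type column order used everywhere a matrix is laid out.
FEATURE_TYPE_ORDER = ("count", "distance", "breadth", "fold_enrichment")

ASSAY_CLASSES = ("epigenetic", "protein_binding")

PEAK_DIALECTS = ("bed3plus", "narrowPeak", "broadPeak")


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakRecord:
    """One called ChIP-seq peak interval (0-based, half-open).

    ``signal_value`` carries the caller's fold enrichment when the dialect
    provides one; ``summit_offset`` is the point-source offset from
    ``start`` (narrowPeak column 10) when non-negative.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    signal_value: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak interval [{self.start}, {self.end}): "
                "start must be >= 0 and < end"
            )
        if self.summit_offset is not None:
            if self.summit_offset < 0:
                raise ValueError("summit_offset must be non-negative")
            if self.start + self.summit_offset >= self.end:
                raise ValueError(
                    f"summit at {self.start + self.summit_offset} falls outside "
                    f"peak [{self.start}, {self.end})"
                )
        if self.signal_value is not None and self.signal_value < 0:
            raise ValueError("signal_value must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Point position used for TSS distance: summit if known, else midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneAnnotationRecord:
    """A gene's TSS anchor: identifier, chromosome, 0-based TSS, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"gene {self.gene_id}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: invalid strand {self.strand!r} "
                "(must be '+' or '-')"
            )


@dataclass(frozen=True)
class DatasetDescriptor:
    """One ChIP-seq dataset in a study manifest."""

    dataset_id: str
    assay_class: str
    label: str
    path: str
    dialect: str = "broadPeak"

    def __post_init__(self) -> None:
        if self.assay_class not in ASSAY_CLASSES:
            raise ValueError(
                f"dataset {self.dataset_id}: assay_class must be one of "
                f"{ASSAY_CLASSES}, got {self.assay_class!r}"
            )
        if self.dialect not in PEAK_DIALECTS:
            raise ValueError(
                f"dataset {self.dataset_id}: unknown peak dialect {self.dialect!r}"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Normalized expression level for one gene (arbitrary non-negative units)."""

    gene_id: str
    expression: float

    def __post_init__(self) -> None:
        if self.expression < 0:
            raise ValueError(f"gene {self.gene_id}: expression must be >= 0")


@dataclass(frozen=True)
class FeatureColumn:
    """Metadata for one feature-matrix column."""

    dataset_id: str
    feature_type: str  # count | distance | breadth | fold_enrichment | expression
    assay_class: str   # epigenetic | protein_binding | expression

    @property
    def column_id(self) -> str:
        return f"{self.dataset_id}.{self.feature_type}"


@dataclass
class FeatureMatrix:
    """Genes x (dataset x feature-type) numeric matrix with column metadata."""

    gene_ids: list[str]
    columns: list[FeatureColumn]
    values: np.ndarray
    normalized: bool = False
    _gene_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.columns)} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_id in feature matrix")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.values[self._gene_index[gene_id]]

    def gene_indices(self, gene_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in gene_ids], dtype=int)

    def select_columns(self, keep: Sequence[int] | Sequence[bool]) -> "FeatureMatrix":
        """New matrix restricted to the given column positions (or boolean mask)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cols = [self.columns[i] for i in keep]
        return FeatureMatrix(
            gene_ids=list(self.gene_ids),
            columns=cols,
            values=self.values[:, keep].copy(),
            normalized=self.normalized,
        )

    def scope_mask(self, scope: str) -> np.ndarray:
        """Boolean column mask for a feature scope."""
        allowed = {
            "epigenetic": {"epigenetic"},
            "protein_binding": {"protein_binding"},
            "combined": {"epigenetic", "protein_binding"},
            "combined_expression": {"epigenetic", "protein_binding", "expression"},
        }
        if scope not in allowed:
            raise ValueError(f"unknown feature scope {scope!r}")
        classes = allowed[scope]
        return np.array([c.assay_class in classes for c in self.columns])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=[c.column_id for c in self.columns],
        )

    def equals(self, other: "FeatureMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.columns == other.columns
            and self.normalized == other.normalized
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# Peak files
# ---------------------------------------------------------------------------

def _parse_coord(token: str, what: str, lineno: int, path) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: non-integer {what} {token!r}") from None


def read_peak_file(path, dialect: str = "bed3plus") -> list[PeakRecord]:
    """Read a peak file into an ordered list of :class:`PeakRecord`.

    Dialects: ``bed3plus`` (first three BED columns; extras ignored except
    column 4 -> name), ``narrowPeak`` (column 7 -> signal_value, column 10
    -> summit_offset when >= 0) and ``broadPeak`` (column 7 -> signal_value,
    no summit).  Lines starting with ``#``, ``track`` or ``browser`` are
    skipped.  Input order is preserved exactly.
    """
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r} (choose from {PEAK_DIALECTS})")
    path = Path(path)
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            chrom = fields[0]
            start = _parse_coord(fields[1], "start", lineno, path)
            end = _parse_coord(fields[2], "end", lineno, path)
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start must be < end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            signal = None
            summit = None
            if dialect in ("narrowPeak", "broadPeak"):
                if len(fields) < 7:
                    raise ValueError(
                        f"{path}:{lineno}: {dialect} requires >= 7 columns, got {len(fields)}"
                    )
                try:
                    signal = float(fields[6])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric signalValue {fields[6]!r}"
                    ) from None
                if signal < 0:
                    signal = None
            if dialect == "narrowPeak":
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(fields)}"
                    )
                pt = _parse_coord(fields[9], "summit offset", lineno, path)
                summit = pt if pt >= 0 else None
            try:
                records.append(
                    PeakRecord(
                        chrom=chrom, start=start, end=end, name=name,
                        signal_value=signal, summit_offset=summit,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_peak_file(peaks: Iterable[PeakRecord], path, dialect: str = "broadPeak") -> None:
    """Write peaks in the given dialect (inverse of :func:`read_peak_file`)."""
    if dialect not in PEAK_DIALECTS:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for pk in peaks:
            name = pk.name if pk.name is not None else "."
            if dialect == "bed3plus":
                fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{name}\n")
                continue
            signal = pk.signal_value if pk.signal_value is not None else -1
            base = f"{pk.chrom}\t{pk.start}\t{pk.end}\t{name}\t0\t.\t{signal:g}\t-1\t-1"
            if dialect == "narrowPeak":
                summit = pk.summit_offset if pk.summit_offset is not None else -1
                fh.write(f"{base}\t{summit}\n")
            else:
                fh.write(f"{base}\n")


# ---------------------------------------------------------------------------
# Gene annotation / gene lists / expression / manifest
# ---------------------------------------------------------------------------

def read_gene_annotation(path) -> list[GeneAnnotationRecord]:
    """Read a TSS annotation table (TSV: gene_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneAnnotationRecord(
                gene_id=row.gene_id, chrom=row.chrom,
                tss=int(row.tss), strand=row.strand,
            )
        )
    return records


def write_gene_annotation(annotation: Iterable[GeneAnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for rec in annotation:
            fh.write(f"{rec.gene_id}\t{rec.chrom}\t{rec.tss}\t{rec.strand}\n")


def read_gene_list(path) -> set[str]:
    """Read a one-id-per-line gene list; duplicates collapse with a warning."""
    seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for line in fh:
            gid = line.strip()
            if not gid:
                continue
            if gid in seen:
                n_dup += 1
            seen.add(gid)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate gene ids", path, n_dup)
    if not seen:
        raise ValueError(f"{path}: empty gene list")
    return seen


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes):
            fh.write(f"{gid}\n")


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene_id, expression."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "expression"):
        if col not in df.columns:
            raise ValueError(f"{path}: expression table missing column {col!r}")
    return [
        ExpressionRecord(gene_id=row.gene_id, expression=float(row.expression))
        for row in df.itertuples(index=False)
    ]


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\texpression\n")
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.expression:.6g}\n")


def read_manifest(path) -> list[DatasetDescriptor]:
    """Read a dataset manifest (TSV: dataset_id, assay_class, label, path, dialect)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"dataset_id", "assay_class", "label", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    dup = df["dataset_id"][df["dataset_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate dataset_id {dup.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DatasetDescriptor(
                dataset_id=row.dataset_id,
                assay_class=row.assay_class,
                label=row.label,
                path=row.path,
                dialect=getattr(row, "dialect", "broadPeak") or "broadPeak",
            )
        )
    return records


def write_manifest(manifest: Iterable[DatasetDescriptor], path) -> None:
    with open(path, "w") as fh:
        fh.write("dataset_id\tassay_class\tlabel\tpath\tdialect\n")
        for d in manifest:
            fh.write(f"{d.dataset_id}\t{d.assay_class}\t{d.label}\t{d.path}\t{d.dialect}\n")


# ---------------------------------------------------------------------------
# Feature matrix TSV (two-line header: column ids, then assay_class:feature_type)
# ---------------------------------------------------------------------------

def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV with a two-line header.

    Line 1: ``gene_id`` then one ``dataset_id.feature_type`` id per column.
    Line 2: ``#normalized=0|1`` then one ``assay_class:feature_type`` tag
    per column.  Non-finite values are written as ``nan``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(c.column_id for c in matrix.columns) + "\n")
        fh.write(
            f"#normalized={int(matrix.normalized)}\t"
            + "\t".join(f"{c.assay_class}:{c.feature_type}" for c in matrix.columns)
            + "\n"
        )
        for gid, row in zip(matrix.gene_ids, matrix.values):
            cells = "\t".join("nan" if not math.isfinite(v) else repr(float(v)) for v in row)
            fh.write(f"{gid}\t{cells}\n")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    ``read(write(m))`` is the identity on values (bit-exact, ``nan``
    restored as missing), gene order, column metadata and the normalized
    flag.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        meta = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene_id":
            raise ValueError(f"{path}: first header line must start with 'gene_id'")
        if not meta or not meta[0].startswith("#normalized="):
            raise ValueError(f"{path}: missing metadata header line (#normalized=...)")
        if len(meta) != len(header):
            raise ValueError(
                f"{path}: metadata header has {len(meta)} fields, expected {len(header)}"
            )
        normalized = bool(int(meta[0].split("=", 1)[1]))
        columns = []
        for col_id, tag in zip(header[1:], meta[1:]):
            if ":" not in tag:
                raise ValueError(f"{path}: malformed column metadata {tag!r}")
            assay_class, feature_type = tag.split(":", 1)
            if "." not in col_id:
                raise ValueError(f"{path}: malformed column id {col_id!r}")
            dataset_id, ft = col_id.rsplit(".", 1)
            if ft != feature_type:
                raise ValueError(
                    f"{path}: column id {col_id!r} disagrees with metadata {tag!r}"
                )
            columns.append(FeatureColumn(dataset_id, feature_type, assay_class))
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: {len(cells)} fields, expected {len(header)}"
                )
            gene_ids.append(cells[0])
            rows.append([float(c) for c in cells[1:]])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(columns)))
    return FeatureMatrix(gene_ids=gene_ids, columns=columns, values=values,
                         normalized=normalized)
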