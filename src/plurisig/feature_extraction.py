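"""Step 1: promoter feature extraction from called ChIP-seq peaks.

Each peak is assigned to the gene with the closest annotated TSS (same
chromosome; peak anchor = summit when known, else interval midpoint).
Per gene and dataset three features are derived:

* ``count`` — number of peaks assigned to the gene (0 if none);
* ``distance`` — signed strand-aware distance (bp) from the TSS to the
  anchor of the closest assigned peak, negative upstream / positive
  downstream in gene orientation;
* ``breadth`` — genomic length (bp) of the broadest assigned peak.

An optional fourth feature, ``fold_enrichment`` (max signal value among
assigned peaks), is off by default.  Genes with no assigned peaks get
count 0, breadth 0 and a large positive distance sentinel encoding "no
nearby peak".  Features from all datasets (plus an optional expression
column) are stacked into a genes x columns matrix and Z-score
normalized column-wise before any model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .peak_io import (
    DatasetDescriptor,
    ExpressionRecord,
    FeatureColumn,
    FeatureMatrix,
    GeneAnnotationRecord,
    PeakRecord,
)

logger = logging.getLogger(__name__)

#: Signed-distance value imputed for genes with no assigned peak (bp).
DISTANCE_SENTINEL = 1_000_000

#: Fold-enrichment value imputed for genes with no assigned peak.
FOLD_ENRICHMENT_MISSING = 0.0

DEFAULT_FEATURE_TYPES = ("count", "distance", "breadth")


@dataclass(frozen=True)
class AssignedPeak:
    """A peak together with its signed distance to its assigned gene's TSS."""

    peak: PeakRecord
    signed_distance: int


@dataclass(frozen=True)
class GeneFeatureTriple:
    """Per-gene per-dataset feature values."""

    count: int
    signed_distance: int
    breadth: int
    fold_enrichment: float = FOLD_ENRICHMENT_MISSING

    def __post_init__(self) -> None:
        if self.count < 0 or self.breadth < 0:
            raise ValueError("count and breadth must be non-negative")
        if self.count == 0 and (self.breadth != 0
                                or self.signed_distance != DISTANCE_SENTINEL):
            raise ValueError(
                "peakless gene must have breadth 0 and the distance sentinel"
            )
        if self.count > 0 and self.breadth < 1:
            raise ValueError("a gene with peaks must have breadth >= 1")


def signed_distance(anchor: int, tss: int, strand: str) -> int:
    """Signed TSS distance in gene orientation (downstream positive)."""
    d = anchor - tss
    return d if strand == "+" else -d


def assign_peaks_to_genes(
    peaks: list[PeakRecord],
    annotation: list[GeneAnnotationRecord],
) -> dict[str, list[AssignedPeak]]:
    """Assign every peak to the gene whose TSS is closest to its anchor.

    Ties on |anchor - tss| go to the lexicographically smaller gene_id.
    Peaks on chromosomes without any annotated gene are dropped (logged
    count).  Every annotated gene appears in the result, possibly with
    an empty list.
    """
    if not annotation:
        raise ValueError("annotation must be nonempty")
    # per-chromosome TSS arrays sorted by (tss, gene_id) for the tie-break
    by_chrom: dict[str, tuple[np.ndarray, list[GeneAnnotationRecord]]] = {}
    for chrom in {g.chrom for g in annotation}:
        genes = sorted(
            (g for g in annotation if g.chrom == chrom),
            key=lambda g: (g.tss, g.gene_id),
        )
        by_chrom[chrom] = (np.array([g.tss for g in genes]), genes)

    out: dict[str, list[AssignedPeak]] = {g.gene_id: [] for g in annotation}
    n_dropped = 0
    for pk in peaks:
        entry = by_chrom.get(pk.chrom)
        if entry is None:
            n_dropped += 1
            continue
        tss_arr, genes = entry
        anchor = pk.anchor
        i = int(np.searchsorted(tss_arr, anchor))
        # minimal |anchor - tss| comes from a sorted neighbour of the
        # insertion point; then collect every gene at that distance so the
        # lexicographic tie-break is exact even with duplicated TSSs
        dist = min(
            abs(anchor - int(tss_arr[j]))
            for j in (i - 1, i)
            if 0 <= j < len(genes)
        )
        lo = int(np.searchsorted(tss_arr, anchor - dist, side="left"))
        hi = int(np.searchsorted(tss_arr, anchor + dist, side="right"))
        best_gene = min(
            (g for g in genes[lo:hi] if abs(anchor - g.tss) == dist),
            key=lambda g: g.gene_id,
        )
        out[best_gene.gene_id].append(
            AssignedPeak(pk, signed_distance(anchor, best_gene.tss, best_gene.strand))
        )
    if n_dropped:
        logger.warning(
            "dropped %d peaks on chromosomes without annotated genes", n_dropped
        )
    return out


def extract_features(
    assignment: dict[str, list[AssignedPeak]],
    annotation: list[GeneAnnotationRecord],
) -> dict[str, GeneFeatureTriple]:
    """Reduce per-gene assigned peaks to (count, signed distance, breadth).

    The reported signed distance is that of the assigned peak with the
    smallest |signed distance|; when two assigned peaks are equally close
    on opposite sides, the downstream (positive) one wins.
    """
    out: dict[str, GeneFeatureTriple] = {}
    for gene in annotation:
        assigned = assignment.get(gene.gene_id, [])
        if not assigned:
            out[gene.gene_id] = GeneFeatureTriple(
                count=0, signed_distance=DISTANCE_SENTINEL, breadth=0,
                fold_enrichment=FOLD_ENRICHMENT_MISSING,
            )
            continue
        # min |d|; tie -> positive (downstream) distance
        best = min(assigned, key=lambda a: (abs(a.signed_distance),
                                            -np.sign(a.signed_distance)))
        breadth = max(a.peak.length for a in assigned)
        signals = [a.peak.signal_value for a in assigned
                   if a.peak.signal_value is not None]
        out[gene.gene_id] = GeneFeatureTriple(
            count=len(assigned),
            signed_distance=best.signed_distance,
            breadth=breadth,
            fold_enrichment=max(signals) if signals else FOLD_ENRICHMENT_MISSING,
        )
    return out


def extract_dataset_features(
    peaks: list[PeakRecord],
    annotation: list[GeneAnnotationRecord],
) -> dict[str, GeneFeatureTriple]:
    """Convenience: assignment followed by feature reduction."""
    return extract_features(assign_peaks_to_genes(peaks, annotation), annotation)


def build_feature_matrix(
    per_dataset_features: dict[str, dict[str, GeneFeatureTriple]],
    manifest: list[DatasetDescriptor],
    annotation: list[GeneAnnotationRecord],
    expression: list[ExpressionRecord] | None = None,
    enabled_features: tuple[str, ...] = DEFAULT_FEATURE_TYPES,
) -> FeatureMatrix:
    """Stack per-dataset feature triples into an unnormalized matrix.

    Column order is manifest order x feature-type order
    (count, distance, breadth[, fold_enrichment]), with the expression
    column, if any, last.
    """
    bad = set(enabled_features) - {"count", "distance", "breadth", "fold_enrichment"}
    if bad:
        raise ValueError(f"unknown feature types: {sorted(bad)}")
    gene_ids = [g.gene_id for g in annotation]
    gene_set = set(gene_ids)
    for d in manifest:
        if d.dataset_id not in per_dataset_features:
            raise ValueError(f"no features for manifest dataset {d.dataset_id!r}")
        covered = set(per_dataset_features[d.dataset_id])
        if covered != gene_set:
            raise ValueError(
                f"dataset {d.dataset_id!r} covers a different gene universe "
                f"({len(covered)} genes vs {len(gene_set)} annotated)"
            )
    order = [ft for ft in ("count", "distance", "breadth", "fold_enrichment")
             if ft in enabled_features]
    columns: list[FeatureColumn] = []
    blocks: list[np.ndarray] = []
    getter = {
        "count": lambda t: float(t.count),
        "distance": lambda t: float(t.signed_distance),
        "breadth": lambda t: float(t.breadth),
        "fold_enrichment": lambda t: float(t.fold_enrichment),
    }
    for d in manifest:
        feats = per_dataset_features[d.dataset_id]
        for ft in order:
            columns.append(FeatureColumn(d.dataset_id, ft, d.assay_class))
            blocks.append(np.array([getter[ft](feats[g]) for g in gene_ids]))
    if expression is not None:
        expr_map = {r.gene_id: r.expression for r in expression}
        missing = gene_set - set(expr_map)
        if missing:
            raise ValueError(
                f"expression table missing {len(missing)} annotated genes "
                f"(e.g. {sorted(missing)[0]!r})"
            )
        columns.append(FeatureColumn("expression", "expression", "expression"))
        blocks.append(np.array([expr_map[g] for g in gene_ids]))
    values = np.column_stack(blocks) if blocks else np.empty((len(gene_ids), 0))
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    return FeatureMatrix(gene_ids=gene_ids, columns=columns, values=values,
                         normalized=False)


def zscore_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Column-wise Z-scores ((x - mean) / population SD) over all genes.

    Zero-variance columns are dropped with a warning; normalizing an
    already-normalized matrix is an error (prevents silent double
    scaling).
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    if matrix.n_columns == 0:
        raise ValueError("matrix has no columns")
    mean = matrix.values.mean(axis=0)
    sd = matrix.values.std(axis=0)  # population SD
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    if not keep.all():
        dropped = [matrix.columns[i].column_id for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d zero-variance columns: %s",
                       len(dropped), ", ".join(dropped))
    values = (matrix.values[:, keep] - mean[keep]) / sd[keep]
    columns = [c for c, k in zip(matrix.columns, keep) if k]
    return FeatureMatrix(gene_ids=list(matrix.gene_ids), columns=columns,
                         values=values, normalized=True)


def study_feature_matrix(study, expression: bool = False,
                         enabled_features: tuple[str, ...] = DEFAULT_FEATURE_TYPES,
                         normalize: bool = True) -> FeatureMatrix:
    """Full Step-1 run on a :class:`~plurisig.synthetic_data.SyntheticStudy`."""
    per_dataset = {
        d.dataset_id: extract_dataset_features(study.peaks[d.dataset_id],
                                               study.annotation)
        for d in study.manifest
    }
    matrix = build_feature_matrix(
        per_dataset, study.manifest, study.annotation,
        expression=study.expression if expression else None,
        enabled_features=enabled_features,
    )
    return zscore_normalize(matrix) if normalize else matrix
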