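"""Downstream evaluation: gene-set overlap, expression shift, feature
correlations and signed-distance distributions.

These are the analyses run on the ensemble's candidate calls: a
one-sided Fisher's exact test for the overlap of two candidate sets on a
shared identifier universe (e.g. human vs mouse predictions), a
Mann-Whitney comparison of candidate expression against the expressed
background, per-dataset Spearman correlations between promoter features
(count vs breadth), and quantile summaries of the signed TSS distances
of signature features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .feature_extraction import DISTANCE_SENTINEL
from .peak_io import ExpressionRecord, FeatureMatrix
from .signature_selection import Signature

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fisher overlap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapTable:
    """2x2 contingency of two gene sets over a finite universe."""

    both: int
    a_only: int
    b_only: int
    neither: int

    def __post_init__(self) -> None:
        if min(self.both, self.a_only, self.b_only, self.neither) < 0:
            raise ValueError("overlap counts must be non-negative")

    @property
    def universe(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither

    @property
    def size_a(self) -> int:
        return self.both + self.a_only

    @property
    def size_b(self) -> int:
        return self.both + self.b_only


@dataclass(frozen=True)
class OverlapResult:
    table: OverlapTable
    p_value: float
    log10_p: float
    odds_ratio: float


def fisher_overlap_from_counts(both: int, size_a: int, size_b: int,
                               universe_size: int) -> OverlapResult:
    """One-sided (enrichment) Fisher's exact test from summary counts.

    The p-value is the hypergeometric upper tail P(X >= both) for X ~
    Hypergeom(universe, size_a, size_b), accumulated in log space so that
    extreme enrichments report a finite log10 p-value even when the
    p-value underflows to 0 in double precision.
    """
    a_only = size_a - both
    b_only = size_b - both
    neither = universe_size - both - a_only - b_only
    if min(both, a_only, b_only, neither) < 0:
        raise ValueError(
            f"inconsistent overlap counts: both={both}, |A|={size_a}, "
            f"|B|={size_b}, universe={universe_size}"
        )
    table = OverlapTable(both, a_only, b_only, neither)
    rv = stats.hypergeom(universe_size, size_a, size_b)
    p = float(rv.sf(both - 1))
    logsf = float(rv.logsf(both - 1))
    log10_p = logsf / math.log(10)
    if a_only == 0 or b_only == 0:
        odds = math.inf if both > 0 else math.nan
    else:
        odds = (both * neither) / (a_only * b_only)
    return OverlapResult(table=table, p_value=p, log10_p=log10_p, odds_ratio=odds)


def fisher_overlap_test(set_a: set[str], set_b: set[str],
                        universe_size: int) -> OverlapResult:
    """One-sided Fisher overlap of two explicit gene sets."""
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set sizes exceed the stated universe")
    return fisher_overlap_from_counts(
        both=len(set_a & set_b), size_a=len(set_a), size_b=len(set_b),
        universe_size=universe_size,
    )


# ---------------------------------------------------------------------------
# Expression comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionComparison:
    statistic: float
    p_value: float
    median_candidates: float
    median_background: float
    n_candidates: int
    n_background: int


def compare_expression(
    candidates: set[str],
    expression: list[ExpressionRecord],
    background: set[str] | None = None,
    expressed_threshold: float = 0.0,
) -> ExpressionComparison:
    """Two-sided Mann-Whitney rank test: candidates vs expressed background.

    The background defaults to all genes in the expression table with
    expression > ``expressed_threshold``; candidate genes are removed
    from it.  Each group must retain at least two members.
    """
    expr = {r.gene_id: r.expression for r in expression}
    if background is None:
        background = {g for g, v in expr.items() if v > expressed_threshold}
    cand_vals = np.array([expr[g] for g in sorted(candidates) if g in expr])
    bg_genes = (set(background) - set(candidates)) & set(expr)
    bg_vals = np.array([expr[g] for g in sorted(bg_genes)])
    if len(cand_vals) < 2 or len(bg_vals) < 2:
        raise ValueError(
            f"too few genes for a rank test: {len(cand_vals)} candidates, "
            f"{len(bg_vals)} background"
        )
    stat, p = stats.mannwhitneyu(cand_vals, bg_vals, alternative="two-sided")
    return ExpressionComparison(
        statistic=float(stat),
        p_value=float(p),
        median_candidates=float(np.median(cand_vals)),
        median_background=float(np.median(bg_vals)),
        n_candidates=len(cand_vals),
        n_background=len(bg_vals),
    )


# ---------------------------------------------------------------------------
# Feature correlations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationPair:
    dataset_id: str  # "pooled" for the all-dataset concatenation
    feature_a: str
    feature_b: str
    spearman_rho: float
    n: int


@dataclass
class CorrelationSummary:
    pairs: list[CorrelationPair]

    def per_dataset(self) -> list[CorrelationPair]:
        return [p for p in self.pairs if p.dataset_id != "pooled"]

    @property
    def mean_rho(self) -> float:
        per = self.per_dataset()
        return float(np.mean([p.spearman_rho for p in per])) if per else math.nan

    @property
    def pooled_rho(self) -> float:
        for p in self.pairs:
            if p.dataset_id == "pooled":
                return p.spearman_rho
        return math.nan


def feature_correlations(
    matrix: FeatureMatrix,
    feature_pair: tuple[str, str] = ("count", "breadth"),
    restrict_to_marked: bool = True,
) -> CorrelationSummary:
    """Per-dataset and pooled Spearman rho between two feature types.

    Requires the unnormalized matrix (raw counts are needed to identify
    marked genes).  With ``restrict_to_marked`` only genes with count >= 1
    in the dataset enter; datasets with fewer than 3 eligible genes are
    skipped with a warning.  Average ranks are used for ties.
    """
    if matrix.normalized:
        raise ValueError("feature correlations require the unnormalized matrix")
    fa, fb = feature_pair
    datasets = []
    for c in matrix.columns:
        if c.feature_type == fa and c.dataset_id not in datasets:
            datasets.append(c.dataset_id)
    col_of = {(c.dataset_id, c.feature_type): j
              for j, c in enumerate(matrix.columns)}
    count_col = {(c.dataset_id, "count"): j for j, c in enumerate(matrix.columns)
                 if c.feature_type == "count"}
    pairs: list[CorrelationPair] = []
    pooled_a: list[np.ndarray] = []
    pooled_b: list[np.ndarray] = []
    for ds in datasets:
        ja = col_of.get((ds, fa))
        jb = col_of.get((ds, fb))
        if ja is None or jb is None:
            continue
        a = matrix.values[:, ja]
        b = matrix.values[:, jb]
        if restrict_to_marked:
            jc = count_col.get((ds, "count"))
            if jc is None:
                raise ValueError(
                    f"dataset {ds}: restrict_to_marked requires a count column"
                )
            mask = matrix.values[:, jc] >= 1
            a, b = a[mask], b[mask]
        if len(a) < 3:
            logger.warning("dataset %s: only %d eligible genes, skipped", ds, len(a))
            continue
        rho = stats.spearmanr(a, b).statistic
        pairs.append(CorrelationPair(ds, fa, fb, float(rho), len(a)))
        pooled_a.append(a)
        pooled_b.append(b)
    if pooled_a:
        a = np.concatenate(pooled_a)
        b = np.concatenate(pooled_b)
        rho = stats.spearmanr(a, b).statistic
        pairs.append(CorrelationPair("pooled", fa, fb, float(rho), len(a)))
    return CorrelationSummary(pairs=pairs)


# ---------------------------------------------------------------------------
# Distance distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceSummary:
    dataset_id: str
    n: int
    quantiles: dict[float, float]  # 0.05/0.25/0.5/0.75/0.95
    fraction_within_10kb: float
    fraction_beyond_100kb: float
    all_missing: bool = False


def distance_distribution_summary(
    matrix: FeatureMatrix,
    signature: Signature,
) -> list[DistanceSummary]:
    """Signed-distance summaries for each signature dataset.

    Sentinel-imputed distances (peakless genes) are excluded; a dataset
    whose distances are all sentinels is flagged ``all_missing``.
    """
    if matrix.normalized:
        raise ValueError("distance summaries require the unnormalized matrix")
    if not signature.entries:
        raise ValueError("signature is empty")
    col_of = {(c.dataset_id, c.feature_type): j
              for j, c in enumerate(matrix.columns)}
    qs = (0.05, 0.25, 0.5, 0.75, 0.95)
    out: list[DistanceSummary] = []
    seen: set[str] = set()
    for entry in signature.entries:
        ds = entry.dataset_id
        if ds in seen:
            continue
        seen.add(ds)
        j = col_of.get((ds, "distance"))
        if j is None:
            continue
        d = matrix.values[:, j]
        d = d[d != DISTANCE_SENTINEL]
        if len(d) == 0:
            out.append(DistanceSummary(ds, 0, {q: math.nan for q in qs},
                                       math.nan, math.nan, all_missing=True))
            continue
        out.append(
            DistanceSummary(
                dataset_id=ds,
                n=len(d),
                quantiles={q: float(np.quantile(d, q)) for q in qs},
                fraction_within_10kb=float(np.mean(np.abs(d) <= 10_000)),
                fraction_beyond_100kb=float(np.mean(np.abs(d) > 100_000)),
            )
        )
    return out
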