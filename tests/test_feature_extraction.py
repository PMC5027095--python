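import numpy as np
import pytest

from plurisig import (
    DISTANCE_SENTINEL,
    GeneAnnotationRecord,
    GeneFeatureTriple,
    PeakRecord,
    assign_peaks_to_genes,
    build_feature_matrix,
    extract_features,
    zscore_normalize,
)
from plurisig.feature_extraction import AssignedPeak, signed_distance
from plurisig.peak_io import DatasetDescriptor, ExpressionRecord


def peak(chrom, start, end, **kw):
    return PeakRecord(chrom=chrom, start=start, end=end, **kw)


class TestAssignment:
    def test_plus_strand_downstream_is_positive(self):
        gA = GeneAnnotationRecord("gA", "chr1", 1000, "+")
        out = assign_peaks_to_genes([peak("chr1", 1100, 1200)], [gA])
        (assigned,) = out["gA"]
        assert assigned.signed_distance == 150  # anchor 1150, downstream

    def test_minus_strand_higher_coordinate_is_upstream(self):
        gB = GeneAnnotationRecord("gB", "chr1", 2000, "-")
        out = assign_peaks_to_genes([peak("chr1", 2100, 2200)], [gB])
        (assigned,) = out["gB"]
        assert assigned.signed_distance == -150

    def test_equidistant_tie_goes_to_smaller_gene_id(self):
        genes = [
            GeneAnnotationRecord("gZ", "chr1", 1000, "+"),
            GeneAnnotationRecord("gA", "chr1", 3000, "+"),
        ]
        out = assign_peaks_to_genes([peak("chr1", 1995, 2005)], genes)
        assert len(out["gA"]) == 1 and len(out["gZ"]) == 0

    def test_summit_overrides_midpoint(self):
        genes = [
            GeneAnnotationRecord("gA", "chr1", 1000, "+"),
            GeneAnnotationRecord("gB", "chr1", 5000, "+"),
        ]
        # midpoint 3000 is nearer gB only by summit: summit at offset 3900
        pk = peak("chr1", 1000, 5000, summit_offset=3900)
        out = assign_peaks_to_genes([pk], genes)
        assert len(out["gB"]) == 1

    def test_unannotated_chromosome_dropped_with_warning(self, caplog):
        gA = GeneAnnotationRecord("gA", "chr1", 1000, "+")
        with caplog.at_level("WARNING"):
            out = assign_peaks_to_genes(
                [peak("chrUn", 0, 10), peak("chr1", 0, 10)], [gA]
            )
        assert len(out["gA"]) == 1
        assert any("dropped 1 peaks" in r.message for r in caplog.records)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_genes = rng.integers(2, 50)
            n_peaks = rng.integers(1, 200)
            chroms = [f"chr{c}" for c in rng.integers(1, 4, size=n_genes)]
            genes = [
                GeneAnnotationRecord(
                    f"g{i:03d}", chroms[i], int(rng.integers(0, 100_000)),
                    "+" if rng.uniform() < 0.5 else "-",
                )
                for i in range(n_genes)
            ]
            peaks = []
            for _ in range(n_peaks):
                start = int(rng.integers(0, 100_000))
                peaks.append(
                    peak(f"chr{rng.integers(1, 4)}", start,
                         start + int(rng.integers(1, 2000)))
                )
            fast = assign_peaks_to_genes(peaks, genes)
            # brute force: all (peak, gene) pairs, min distance then gene_id
            expected = {g.gene_id: [] for g in genes}
            for pk in peaks:
                cands = [g for g in genes if g.chrom == pk.chrom]
                if not cands:
                    continue
                best = min(cands,
                           key=lambda g: (abs(pk.anchor - g.tss), g.gene_id))
                expected[best.gene_id].append(pk)
            got = {g: [a.peak for a in v] for g, v in fast.items()}
            assert got == expected

    def test_strand_flip_negates_distances(self):
        rng = np.random.default_rng(7)
        genes = [GeneAnnotationRecord(f"g{i}", "chr1", 10_000 * (i + 1), "+")
                 for i in range(5)]
        flipped = [GeneAnnotationRecord(g.gene_id, g.chrom, g.tss, "-")
                   for g in genes]
        peaks = [peak("chr1", int(s), int(s) + 100)
                 for s in rng.integers(0, 60_000, size=40)]
        d_plus = {g: [a.signed_distance for a in v]
                  for g, v in assign_peaks_to_genes(peaks, genes).items()}
        d_minus = {g: [a.signed_distance for a in v]
                   for g, v in assign_peaks_to_genes(peaks, flipped).items()}
        for g in d_plus:
            assert d_minus[g] == [-d for d in d_plus[g]]

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        genes = [GeneAnnotationRecord(f"g{i}", "chr1", int(t), "+")
                 for i, t in enumerate(sorted(rng.integers(0, 50_000, size=8)))]
        peaks = [peak("chr1", int(s), int(s) + 50)
                 for s in rng.integers(0, 60_000, size=100)]
        feats = extract_features(assign_peaks_to_genes(peaks, genes), genes)
        assert sum(t.count for t in feats.values()) == len(peaks)


class TestExtractFeatures:
    def _gene(self):
        return GeneAnnotationRecord("gA", "chr1", 1000, "+")

    def test_count_breadth_closest_distance(self):
        g = self._gene()
        assignment = {
            "gA": [
                AssignedPeak(peak("chr1", 900, 1400), 150),     # length 500
                AssignedPeak(peak("chr1", 100, 220), -9000),    # length 120
            ]
        }
        t = extract_features(assignment, [g])["gA"]
        assert (t.count, t.breadth, t.signed_distance) == (2, 500, 150)

    def test_no_peaks_gets_sentinel(self):
        t = extract_features({"gA": []}, [self._gene()])["gA"]
        assert (t.count, t.breadth, t.signed_distance) == (0, 0, DISTANCE_SENTINEL)

    def test_peak_at_tss_has_zero_distance(self):
        assignment = {"gA": [AssignedPeak(peak("chr1", 950, 1050), 0)]}
        t = extract_features(assignment, [self._gene()])["gA"]
        assert t.signed_distance == 0

    def test_equal_absolute_distance_prefers_downstream(self):
        assignment = {
            "gA": [
                AssignedPeak(peak("chr1", 800, 900), -150),
                AssignedPeak(peak("chr1", 1100, 1200), 150),
            ]
        }
        t = extract_features(assignment, [self._gene()])["gA"]
        assert t.signed_distance == 150

    def test_fold_enrichment_is_max_signal(self):
        assignment = {
            "gA": [
                AssignedPeak(peak("chr1", 900, 1000, signal_value=2.0), -50),
                AssignedPeak(peak("chr1", 1100, 1200, signal_value=7.5), 150),
            ]
        }
        t = extract_features(assignment, [self._gene()])["gA"]
        assert t.fold_enrichment == 7.5

    def test_triple_invariants(self):
        with pytest.raises(ValueError):
            GeneFeatureTriple(count=0, signed_distance=0, breadth=0)
        with pytest.raises(ValueError):
            GeneFeatureTriple(count=2, signed_distance=10, breadth=0)


def _features_for(genes, value=1.0):
    return {
        g.gene_id: GeneFeatureTriple(count=1, signed_distance=int(value),
                                     breadth=100)
        for g in genes
    }


class TestBuildMatrix:
    def _setup(self, n_genes=10, n_datasets=4):
        genes = [GeneAnnotationRecord(f"g{i:02d}", "chr1", 1000 * (i + 1), "+")
                 for i in range(n_genes)]
        manifest = [
            DatasetDescriptor(f"d{j}", "epigenetic" if j % 2 else
                              "protein_binding", f"d{j}", f"d{j}.bed")
            for j in range(n_datasets)
        ]
        per_dataset = {d.dataset_id: _features_for(genes) for d in manifest}
        return genes, manifest, per_dataset

    def test_layout_10x12(self):
        genes, manifest, per_dataset = self._setup()
        m = build_feature_matrix(per_dataset, manifest, genes)
        assert m.values.shape == (10, 12)
        assert [c.feature_type for c in m.columns[:3]] == [
            "count", "distance", "breadth"
        ]

    def test_expression_column_is_last(self):
        genes, manifest, per_dataset = self._setup()
        expr = [ExpressionRecord(g.gene_id, 5.0) for g in genes]
        m = build_feature_matrix(per_dataset, manifest, genes, expression=expr)
        assert m.values.shape == (10, 13)
        assert m.columns[-1].assay_class == "expression"

    def test_gene_universe_mismatch_is_error(self):
        genes, manifest, per_dataset = self._setup()
        del per_dataset["d0"][genes[0].gene_id]
        with pytest.raises(ValueError, match="universe"):
            build_feature_matrix(per_dataset, manifest, genes)

    def test_peakless_dataset_columns(self):
        genes, manifest, per_dataset = self._setup(n_datasets=2)
        per_dataset["d0"] = {
            g.gene_id: GeneFeatureTriple(0, DISTANCE_SENTINEL, 0) for g in genes
        }
        m = build_feature_matrix(per_dataset, manifest, genes)
        assert (m.values[:, 0] == 0).all()                  # counts
        assert (m.values[:, 1] == DISTANCE_SENTINEL).all()  # distances
        assert (m.values[:, 2] == 0).all()                  # breadths


class TestZScore:
    def test_closed_form(self):
        genes, manifest, per_dataset = TestBuildMatrix()._setup(3, 1)
        m = build_feature_matrix(per_dataset, manifest, genes)
        m.values[:, 0] = [1.0, 2.0, 3.0]
        m.values[:, 1] = [0.0, 1.0, 2.0]  # keep nonconstant
        m.values[:, 2] = [5.0, 6.0, 7.0]
        z = zscore_normalize(m)
        expected = np.array([-1.224744871391589, 0.0, 1.224744871391589])
        np.testing.assert_allclose(z.values[:, 0], expected, atol=1e-12)
        assert z.normalized

    def test_columns_standardized_and_constant_dropped(self, caplog):
        genes, manifest, per_dataset = TestBuildMatrix()._setup(5, 2)
        m = build_feature_matrix(per_dataset, manifest, genes)
        m.values[:] = np.random.default_rng(0).normal(size=m.values.shape)
        m.values[:, 3] = 5.0  # constant column
        with caplog.at_level("WARNING"):
            z = zscore_normalize(m)
        assert z.n_columns == m.n_columns - 1
        np.testing.assert_allclose(z.values.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(z.values.std(axis=0), 1, atol=1e-8)
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_double_normalization_rejected(self):
        genes, manifest, per_dataset = TestBuildMatrix()._setup(4, 1)
        m = build_feature_matrix(per_dataset, manifest, genes)
        m.values[:] = np.random.default_rng(1).normal(size=m.values.shape)
        z = zscore_normalize(m)
        with pytest.raises(ValueError, match="already normalized"):
            zscore_normalize(z)

    def test_all_constant_is_error(self):
        genes, manifest, per_dataset = TestBuildMatrix()._setup(4, 1)
        m = build_feature_matrix(per_dataset, manifest, genes)
        m.values[:] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            zscore_normalize(m)


def test_signed_distance_convention():
    assert signed_distance(1150, 1000, "+") == 150
    assert signed_distance(1150, 1000, "-") == -150
    assert signed_distance(900, 1000, "-") == 100
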