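"""Nonredundant gene selection, expression tertiles, promoters and TSS
profiles."""

import numpy as np
import pytest

from tfclust.core import Genome, GenomicInterval
from tfclust.clustering import Cluster, ClusterConfig, Peak, build_clusters
from tfclust.genes import (
    ContextLabel,
    ExpressionClass,
    Gene,
    GeneContextAssigner,
    classify_expression,
    promoter_interval,
    read_refgene,
    select_nonredundant,
    tss_profile,
    write_refgene,
)


def _gene(gid, tx_start, tx_end, strand="+", expression=0.0, chrom="chr1", exons=None):
    if exons is None:
        exons = ((tx_start, tx_start + 100), (tx_end - 100, tx_end))
    return Gene(gid, chrom, strand, tx_start, tx_end, tuple(exons), expression)


GENOME = Genome({"chr1": 1_000_000})


class TestSelectNonredundant:
    def test_same_strand_exon_overlap_keeps_highest_expression(self):
        a = _gene("A", 1000, 5000, "+", 5.0, exons=((1000, 1500),))
        b = _gene("B", 1200, 6000, "+", 3.0, exons=((1200, 1600),))
        assert [g.id for g in select_nonredundant([a, b])] == ["A"]

    def test_opposite_strands_both_retained(self):
        a = _gene("A", 1000, 5000, "+", 5.0, exons=((1000, 1500),))
        b = _gene("B", 1200, 6000, "-", 3.0, exons=((1200, 1600),))
        assert len(select_nonredundant([a, b])) == 2

    def test_transitive_grouping(self):
        # A overlaps B, B overlaps C, A and C share no exon -> one survivor
        a = _gene("A", 1000, 2000, "+", 1.0, exons=((1000, 1300),))
        b = _gene("B", 1200, 2500, "+", 9.0, exons=((1200, 1600),))
        c = _gene("C", 1500, 3000, "+", 2.0, exons=((1500, 1800),))
        assert [g.id for g in select_nonredundant([a, b, c])] == ["B"]

    def test_single_gene_is_itself(self):
        g = _gene("A", 1000, 2000)
        assert select_nonredundant([g]) == [g]

    def test_no_same_strand_overlap_remains(self):
        rng = np.random.default_rng(0)
        genes = []
        for i in range(60):
            start = int(rng.integers(0, 500_000))
            genes.append(
                _gene(
                    f"G{i}",
                    start,
                    start + 2000,
                    "+" if rng.random() < 0.5 else "-",
                    float(rng.random()),
                    exons=((start, start + 500), (start + 1500, start + 2000)),
                )
            )
        kept = select_nonredundant(genes)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                if a.strand != b.strand or a.chrom != b.chrom:
                    continue
                for s1, e1 in a.exons:
                    for s2, e2 in b.exons:
                        assert not (s1 < e2 and s2 < e1)


class TestClassifyExpression:
    def test_tertile_and_zero_classes(self):
        exprs = [10, 9, 8, 7, 6, 5, 4, 3, 0]
        genes = [_gene(f"G{i}", 1000 * i + 1000, 1000 * i + 1500, expression=float(e))
                 for i, e in enumerate(exprs)]
        classes = classify_expression(genes)
        assert [classes[f"G{i}"] for i in range(3)] == [ExpressionClass.HIGH] * 3
        assert classes["G8"] is ExpressionClass.ZERO
        assert classes["G5"] is ExpressionClass.MEDIUM_LOW

    def test_all_zero_means_no_high(self):
        genes = [_gene(f"G{i}", 1000 * i + 1000, 1000 * i + 1500) for i in range(6)]
        classes = classify_expression(genes)
        assert set(classes.values()) == {ExpressionClass.ZERO}

    def test_floor_behaviour_small_n(self):
        genes = [
            _gene("A", 1000, 1500, expression=5.0),
            _gene("B", 3000, 3500, expression=4.0),
        ]
        classes = classify_expression(genes)
        assert ExpressionClass.HIGH not in classes.values()

    def test_classes_partition_gene_set(self, default_dataset):
        classes = classify_expression(default_dataset.genes)
        assert set(classes) == {g.id for g in default_dataset.genes}


class TestPromoterInterval:
    def test_plus_strand_window(self):
        g = _gene("A", 10_000, 20_000, "+")
        iv = promoter_interval(g, GENOME)
        assert (iv.start, iv.end) == (8000, 10_200)

    def test_minus_strand_mirror(self):
        g = _gene("A", 2000, 10_000, "-")
        iv = promoter_interval(g, GENOME)
        assert (iv.start, iv.end) == (9800, 12_000)

    def test_mirror_images_about_shared_tss(self):
        plus = promoter_interval(_gene("A", 10_000, 20_000, "+"), GENOME)
        minus = promoter_interval(_gene("B", 2000, 10_000, "-"), GENOME)
        # reflect the minus window about TSS=10,000
        assert (2 * 10_000 - minus.end, 2 * 10_000 - minus.start) == (plus.start, plus.end)

    def test_clamped_near_chromosome_start(self):
        g = _gene("A", 1000, 5000, "+")
        iv = promoter_interval(g, GENOME)
        assert (iv.start, iv.end) == (0, 1200)


def _cluster_at(center, half=500):
    region = GenomicInterval("chr1", center - half, center + half)
    peak = Peak(GenomicInterval("chr1", center - 50, center + 50), "F", 1.0, "p")
    return Cluster(region=region, peaks=[peak, peak])


class TestGeneContext:
    GENES = [_gene("A", 100_000, 120_000, "+", 5.0)]

    def _assign(self, cluster):
        return GeneContextAssigner(self.GENES, GENOME).assign(cluster)

    def test_cluster_near_tss_is_promoter(self):
        ctx = self._assign(_cluster_at(100_000 - 500))
        assert ctx.label is ContextLabel.PROMOTER and ctx.gene_id == "A"

    def test_cluster_5kb_upstream_is_gene(self):
        ctx = self._assign(_cluster_at(100_000 - 5000, half=200))
        assert ctx.label is ContextLabel.GENE

    def test_cluster_in_body_outside_promoter_is_gene(self):
        ctx = self._assign(_cluster_at(110_000, half=200))
        assert ctx.label is ContextLabel.GENE

    def test_far_cluster_is_intergenic(self):
        ctx = self._assign(_cluster_at(500_000))
        assert ctx.label is ContextLabel.INTERGENIC and ctx.gene_id is None

    def test_nearest_tss_wins(self):
        genes = [
            _gene("A", 100_000, 120_000, "+", 5.0),
            _gene("B", 101_500, 130_000, "+", 1.0, exons=((110_000, 110_500),)),
        ]
        # cluster overlaps both promoter windows; A's TSS is closer
        ctx = GeneContextAssigner(genes, GENOME).assign(_cluster_at(100_100))
        assert ctx.label is ContextLabel.PROMOTER and ctx.gene_id == "A"


class TestTssProfile:
    def test_midpoint_downstream_of_plus_tss(self):
        g = _gene("A", 10_000, 20_000, "+")
        regions = [GenomicInterval("chr1", 10_100, 10_200)]  # midpoint 10,150
        counts = tss_profile(regions, [g], window=2000, bin=200)
        assert counts.sum() == 1
        assert counts[2000 // 200] == 1  # bin [0, 200)

    def test_minus_strand_mirrors_distance(self):
        g = _gene("A", 2000, 10_000, "-")
        regions = [GenomicInterval("chr1", 10_100, 10_200)]  # 150 downstream of TSS
        counts = tss_profile(regions, [g], window=2000, bin=200)
        assert counts[(2000 - 200) // 200] == 1  # bin [-200, 0)

    def test_empty_regions_zero_vector(self):
        g = _gene("A", 10_000, 20_000, "+")
        counts = tss_profile([], [g], window=2000, bin=200)
        assert counts.shape == (20,) and not counts.any()

    def test_window_must_divide(self):
        with pytest.raises(ValueError):
            tss_profile([], [], window=1000, bin=300)

    def test_promoter_planted_clusters_concentrate_at_active_tss(self):
        """When elements sit only at promoters of high-expression genes, the
        profile piles up in [-2000, +200) around those genes and is flat at
        silent ones."""
        from tfclust import SyntheticConfig, generate
        from tfclust.simulate import DEFAULT_ELEMENT_COUNTS, ElementClass

        counts = {c: 0 for c in DEFAULT_ELEMENT_COUNTS}
        counts[ElementClass.ACTIVE_PROMOTER] = 60
        ds = generate(SyntheticConfig(seed=5, element_counts=counts, noise_peaks_per_mb=0.0))
        clusters, _ = build_clusters(ds.all_peaks, ClusterConfig(), ds.genome)
        classes = classify_expression(ds.genes)
        regions = [cl.region for cl in clusters]
        high = [g for g in ds.genes if classes[g.id] is ExpressionClass.HIGH]
        zero = [g for g in ds.genes if classes[g.id] is ExpressionClass.ZERO]
        prof_high = tss_profile(regions, high, window=4000, bin=200)
        prof_zero = tss_profile(regions, zero, window=4000, bin=200)
        window_bins = slice((4000 - 2000) // 200, (4000 + 200) // 200)
        assert prof_high[window_bins].sum() >= 0.8 * prof_high.sum()
        assert prof_zero.sum() <= 0.05 * prof_high.sum()


class TestRefgeneIO:
    def test_round_trip_with_expression(self, tmp_path):
        genes = [
            _gene("A", 1000, 5000, "+", 2.5, exons=((1000, 1400), (4000, 5000))),
            _gene("B", 9000, 12_000, "-", 0.0, exons=((9000, 9500),)),
        ]
        path = tmp_path / "genes.tsv"
        write_refgene(genes, path, with_expression=True)
        back = read_refgene(path)
        assert back == genes
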