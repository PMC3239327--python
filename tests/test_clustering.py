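"""Cluster construction, the shuffle null and the scipy connected-components
oracle."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from tfclust.clustering import (
    ClusterConfig,
    Peak,
    bin_peaks_by_intensity,
    build_clusters,
    cluster_size_histogram,
    extend_peak,
    mean_length_by_size,
    read_peaks,
    shuffle_peaks,
)
from tfclust.core import Genome, GenomicInterval


def _peak(chrom, start, end, factor="F", intensity=1.0, pid=""):
    return Peak(GenomicInterval(chrom, start, end), factor, intensity, pid or f"{factor}:{start}")


def _random_peaks(rng, n, genome):
    chroms = list(genome)
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome[chrom] - 500))
        length = int(rng.integers(100, 500))
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, start + length),
                factor=f"F{int(rng.integers(0, 5))}",
                intensity=float(rng.random()),
                source_id=f"p{i}",
            )
        )
    return peaks


def _oracle_components(peaks, config, genome):
    """Connected components of the pairwise extended-overlap graph (scipy)."""
    ext = [extend_peak(p, config.extension_length, genome) for p in peaks]
    n = len(ext)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if ext[i].overlaps(ext[j]):
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    comps = {}
    for i, lab in enumerate(labels):
        comps.setdefault(lab, set()).add(peaks[i].source_id)
    return {frozenset(c) for c in comps.values()}


class TestExtendPeak:
    def test_symmetric_about_midpoint(self, toy_genome):
        iv = extend_peak(_peak("chr1", 5000, 5100), 2000, toy_genome)
        assert (iv.start, iv.end) == (4050, 6050)

    def test_clamped_at_chromosome_start(self, toy_genome):
        iv = extend_peak(_peak("chr1", 0, 100), 2000, toy_genome)
        assert (iv.start, iv.end) == (0, 1050)

    def test_long_peak_unchanged(self, toy_genome):
        iv = extend_peak(_peak("chr1", 1000, 4000), 2000, toy_genome)
        assert (iv.start, iv.end) == (1000, 4000)

    def test_unknown_chromosome_errors(self, toy_genome):
        with pytest.raises(KeyError):
            extend_peak(_peak("chrX", 0, 100), 2000, toy_genome)


class TestBuildClusters:
    def test_two_peaks_within_extension_form_one_cluster(self, toy_genome):
        peaks = [_peak("chr1", 5000, 5100, "A"), _peak("chr1", 6000, 6100, "B")]
        clusters, singles = build_clusters(peaks, ClusterConfig(), toy_genome)
        assert len(clusters) == 1 and len(singles) == 0
        assert clusters[0].size == 2
        assert (clusters[0].region.start, clusters[0].region.end) == (4050, 7050)
        assert clusters[0].factors == {"A", "B"}

    def test_distant_peak_becomes_singleton(self, toy_genome):
        peaks = [
            _peak("chr1", 5000, 5100, "A"),
            _peak("chr1", 6000, 6100, "B"),
            _peak("chr1", 9000, 9100, "C"),
        ]
        clusters, singles = build_clusters(peaks, ClusterConfig(), toy_genome)
        assert len(clusters) == 1 and len(singles) == 1
        assert singles[0].size == 1

    def test_empty_input(self, toy_genome):
        assert build_clusters([], ClusterConfig(), toy_genome) == ([], [])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_connected_components_oracle(self, seed):
        genome = Genome({"chr1": 300_000, "chr2": 200_000})
        rng = np.random.default_rng(seed)
        peaks = _random_peaks(rng, int(rng.integers(2, 150)), genome)
        config = ClusterConfig()
        clusters, singles = build_clusters(peaks, config, genome)
        got = {frozenset(p.source_id for p in cl.peaks) for cl in clusters + singles}
        assert got == _oracle_components(peaks, config, genome)

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_property(self, seed):
        genome = Genome({"chr1": 500_000})
        rng = np.random.default_rng(seed)
        peaks = _random_peaks(rng, 200, genome)
        clusters, singles = build_clusters(peaks, ClusterConfig(), genome)
        assert sum(c.size for c in clusters) + sum(s.size for s in singles) == len(peaks)

    def test_raising_size_limit_only_removes_clusters(self, default_dataset):
        ds = default_dataset
        c2, _ = build_clusters(ds.all_peaks, ClusterConfig(min_cluster_size=2), ds.genome)
        c3, _ = build_clusters(ds.all_peaks, ClusterConfig(min_cluster_size=3), ds.genome)
        ids2 = {frozenset(p.source_id for p in c.peaks) for c in c2}
        ids3 = {frozenset(p.source_id for p in c.peaks) for c in c3}
        assert ids3 <= ids2


class TestShufflePeaks:
    def test_conserves_per_chromosome_length_multiset(self, toy_genome):
        rng = np.random.default_rng(0)
        peaks = _random_peaks(rng, 100, toy_genome)
        shuffled = shuffle_peaks(peaks, toy_genome, 0.88, seed=5)
        before = sorted((p.interval.chrom, p.interval.length, p.factor) for p in peaks)
        after = sorted((p.interval.chrom, p.interval.length, p.factor) for p in shuffled)
        assert before == after

    def test_deterministic_and_seed_sensitive(self, toy_genome):
        rng = np.random.default_rng(1)
        peaks = _random_peaks(rng, 50, toy_genome)
        a = shuffle_peaks(peaks, toy_genome, 0.88, seed=7)
        b = shuffle_peaks(peaks, toy_genome, 0.88, seed=7)
        c = shuffle_peaks(peaks, toy_genome, 0.88, seed=8)
        assert [p.interval for p in a] == [p.interval for p in b]
        assert [p.interval for p in a] != [p.interval for p in c]

    def test_starts_respect_mappability_bound(self):
        genome = Genome({"chr1": 1_000_000})
        peaks = [_peak("chr1", 0, 100, pid=f"p{i}") for i in range(500)]
        shuffled = shuffle_peaks(peaks, genome, 0.88, seed=3)
        starts = [p.interval.start for p in shuffled]
        assert max(starts) <= 879_900 and min(starts) >= 0

    def test_peak_longer_than_mappable_span_errors(self):
        genome = Genome({"chr1": 1000})
        with pytest.raises(ValueError):
            shuffle_peaks([_peak("chr1", 0, 900)], genome, 0.5, seed=0)


class TestSummaries:
    def test_histogram_counts_and_conservation(self, toy_genome):
        peaks = [
            _peak("chr1", 5000, 5100, "A"),
            _peak("chr1", 6000, 6100, "B"),
            _peak("chr1", 50_000, 50_100, "A"),
            _peak("chr1", 100_000, 100_100, "B"),
        ]
        clusters, singles = build_clusters(peaks, ClusterConfig(), toy_genome)
        hist = cluster_size_histogram(clusters, singles)
        assert hist == {1: 2, 2: 1}
        assert sum(size * count for size, count in hist.items()) == len(peaks)

    def test_histogram_empty(self):
        assert cluster_size_histogram([], []) == {}

    def test_singleton_length_floors_at_extension(self, toy_genome):
        clusters, singles = build_clusters([_peak("chr1", 5000, 5100)], ClusterConfig(), toy_genome)
        lengths = mean_length_by_size(clusters, singles)
        assert lengths == {1: 2000.0}

    def test_planted_clusters_shorter_than_shuffled(self, default_dataset, default_clusters):
        """The length contrast between real and shuffled clusters: co-planted
        peaks sit closer together than chance placements."""
        ds = default_dataset
        clusters, singles = default_clusters
        shuffled = shuffle_peaks(ds.all_peaks, ds.genome, 0.88, seed=1)
        s_cl, s_sg = build_clusters(shuffled, ClusterConfig(), ds.genome)
        real = mean_length_by_size(clusters, singles)
        null = mean_length_by_size(s_cl, s_sg)
        common = [s for s in real if s in null and s >= 3]
        assert common, "no shared size classes"
        assert all(null[s] >= real[s] for s in common)


class TestIntensityBins:
    def test_forty_peaks_twenty_bins(self):
        peaks = [_peak("chr1", 100 * i, 100 * i + 50, intensity=float(i), pid=f"p{i}") for i in range(40)]
        bins = bin_peaks_by_intensity(peaks, 20)
        counts = {}
        for b in bins.values():
            counts[b] = counts.get(b, 0) + 1
        assert all(c == 2 for c in counts.values())
        assert bins["p39"] == 20 and bins["p38"] == 20
        assert bins["p0"] == 1

    def test_one_peak_per_bin(self):
        peaks = [_peak("chr1", 100 * i, 100 * i + 50, intensity=float(i), pid=f"p{i}") for i in range(20)]
        bins = bin_peaks_by_intensity(peaks, 20)
        assert sorted(bins.values()) == list(range(1, 21))

    def test_ties_fill_by_stable_order(self):
        peaks = [_peak("chr1", 100 * i, 100 * i + 50, intensity=5.0, pid=f"p{i}") for i in range(10)]
        bins = bin_peaks_by_intensity(peaks, 4)
        sizes = sorted(
            sum(1 for b in bins.values() if b == k) for k in range(1, 5)
        )
        assert max(sizes) - min(sizes) <= 1
        assert bins["p0"] == 1  # stable order: first peak in lowest bin

    def test_monotone_bins(self):
        rng = np.random.default_rng(2)
        peaks = [
            _peak("chr1", 100 * i, 100 * i + 50, intensity=float(rng.random()), pid=f"p{i}")
            for i in range(57)
        ]
        bins = bin_peaks_by_intensity(peaks, 20)
        by_bin = {}
        for p in peaks:
            by_bin.setdefault(bins[p.source_id], []).append(p.intensity)
        for k in range(1, 20):
            assert max(by_bin[k]) <= min(by_bin[k + 1])


class TestPeakIO:
    def test_read_bed5(self, tmp_path):
        p = tmp_path / "MYC.bed"
        p.write_text("chr1\t100\t300\tpk1\t12.5\nchr1\t500\t700\n")
        peaks = read_peaks(p)
        assert peaks[0].factor == "MYC"
        assert peaks[0].intensity == 12.5
        assert peaks[0].source_id == "pk1"
        assert peaks[1].intensity == 0.0
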