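"""Transcription-factor cluster construction and the shuffle null model.

A peak called for one factor is extended to a fixed total length (default
2,000 bp, symmetric about its midpoint) to emulate the span of a typical
regulatory element; peaks whose extended intervals overlap are assigned to
the same cluster (connected components of the extended-overlap graph).
Regions holding at least ``min_cluster_size`` peaks (default 2) are clusters;
the rest are singletons.  The null model shuffles peak starts uniformly
within each chromosome, with the placeable span scaled by a short-read
mappability factor (0.88 for 25-bp tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Genome, GenomicInterval

__all__ = [
    "Peak",
    "ClusterConfig",
    "Cluster",
    "read_peaks",
    "write_clusters",
    "extend_peak",
    "build_clusters",
    "shuffle_peaks",
    "cluster_size_histogram",
    "mean_length_by_size",
    "bin_peaks_by_intensity",
]


@dataclass(frozen=True)
class Peak:
    """A factor-labelled ChIP-Seq peak with a tag-intensity score."""

    interval: GenomicInterval
    factor: str
    intensity: float = 0.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor name must be nonempty")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class ClusterConfig:
    """Parameters of cluster construction and the shuffle null.

    extension_length : total length each peak is extended to, bp.
    min_cluster_size : minimum member count for a region to be a cluster.
    mappability : fraction of each chromosome treated as placeable when
        shuffling (0.88 for 25-bp reads).
    """

    extension_length: int = 2000
    min_cluster_size: int = 2
    mappability: float = 0.88

    def __post_init__(self) -> None:
        if self.extension_length <= 0:
            raise ValueError("extension_length must be > 0")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if not (0 < self.mappability <= 1):
            raise ValueError("mappability must be in (0, 1]")


@dataclass(eq=False)
class Cluster:
    """A merged region of extended peaks.

    ``region`` is the union of the member peaks' extended intervals (a single
    contiguous span, since members form a connected overlap component).
    Hashable by identity so clusters can key dictionaries downstream.
    """

    region: GenomicInterval
    peaks: list[Peak] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.peaks)

    @property
    def factors(self) -> frozenset[str]:
        return frozenset(p.factor for p in self.peaks)


def extend_peak(peak: Peak, total_length: int, genome: Genome) -> GenomicInterval:
    """Extend a peak symmetrically about its midpoint to ``total_length`` bp.

    Peaks already at least ``total_length`` long are returned unchanged.  The
    extended interval is clamped (truncated, not shifted) to chromosome
    bounds.
    """
    if total_length <= 0:
        raise ValueError("total_length must be > 0")
    iv = peak.interval
    chrom_len = genome[iv.chrom]  # raises KeyError for unknown chromosome
    if iv.length >= total_length:
        return iv
    mid = iv.midpoint
    start = mid - total_length // 2
    end = start + total_length
    return GenomicInterval(iv.chrom, max(0, start), min(chrom_len, end))


def build_clusters(
    peaks: list[Peak], config: ClusterConfig, genome: Genome
) -> tuple[list[Cluster], list[Cluster]]:
    """Partition peaks into clusters and singletons.

    Clusters are the connected components of the graph in which two peaks
    are joined when their extended intervals share at least one base.
    Components with at least ``config.min_cluster_size`` members become
    clusters; smaller components (singletons for the default size limit of 2)
    are returned separately.  Every input peak lands in exactly one of the
    two lists.
    """
    if not peaks:
        return [], []
    extended = [extend_peak(p, config.extension_length, genome) for p in peaks]
    order = sorted(range(len(peaks)), key=lambda i: (extended[i].chrom, extended[i].start, extended[i].end))

    clusters: list[Cluster] = []
    small: list[Cluster] = []

    def flush(members: list[int], lo: int, hi: int, chrom: str) -> None:
        cl = Cluster(
            region=GenomicInterval(chrom, lo, hi),
            peaks=[peaks[i] for i in members],
        )
        (clusters if cl.size >= config.min_cluster_size else small).append(cl)

    members: list[int] = []
    cur_chrom = ""
    lo = hi = 0
    for i in order:
        iv = extended[i]
        # strict overlap: touching extended intervals share no base
        if members and iv.chrom == cur_chrom and iv.start < hi:
            members.append(i)
            hi = max(hi, iv.end)
        else:
            if members:
                flush(members, lo, hi, cur_chrom)
            members = [i]
            cur_chrom, lo, hi = iv.chrom, iv.start, iv.end
    flush(members, lo, hi, cur_chrom)
    return clusters, small


def shuffle_peaks(
    peaks: list[Peak],
    genome: Genome,
    mappability: float = 0.88,
    seed: int | np.random.Generator = 0,
) -> list[Peak]:
    """Place each peak at a uniform random start within its chromosome.

    Peak lengths, factor labels and intensities are preserved; only starts
    move.  The placeable span of a chromosome of length L is
    ``floor(mappability * L)``, so starts are drawn uniformly from
    ``[0, mappability*L - length]`` inclusive.  Peaks are placed
    independently; chance overlap between shuffled peaks is allowed (it is
    the point of the null).  Deterministic given the seed.
    """
    if not (0 < mappability <= 1):
        raise ValueError("mappability must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled: list[Peak] = []
    for p in peaks:
        iv = p.interval
        span = int(mappability * genome[iv.chrom])
        max_start = span - iv.length
        if max_start < 0:
            raise ValueError(
                f"peak of length {iv.length} does not fit mappable span {span} "
                f"of chromosome {iv.chrom}"
            )
        start = int(rng.integers(0, max_start, endpoint=True))
        shuffled.append(
            Peak(
                interval=GenomicInterval(iv.chrom, start, start + iv.length),
                factor=p.factor,
                intensity=p.intensity,
                source_id=p.source_id,
            )
        )
    return shuffled


def cluster_size_histogram(
    clusters: list[Cluster], singletons: list[Cluster]
) -> dict[int, int]:
    """Count regions per member-count size class, keyed from 1 upward."""
    hist: dict[int, int] = {}
    for cl in list(clusters) + list(singletons):
        hist[cl.size] = hist.get(cl.size, 0) + 1
    return dict(sorted(hist.items()))


def mean_length_by_size(
    clusters: list[Cluster], singletons: list[Cluster]
) -> dict[int, float]:
    """Mean merged-region length (bp) per cluster size class."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for cl in list(clusters) + list(singletons):
        sums[cl.size] = sums.get(cl.size, 0.0) + cl.region.length
        counts[cl.size] = counts.get(cl.size, 0) + 1
    return {size: sums[size] / counts[size] for size in sorted(sums)}


def bin_peaks_by_intensity(peaks: list[Peak], n_bins: int) -> dict[str, int]:
    """Assign peaks of one factor dataset to equal-count intensity bins.

    Bins are quantile (equal-occupancy) bins numbered 1..n_bins with the most
    intense peaks in bin ``n_bins``; sizes differ by at most one and ties are
    broken by stable input order.  Returns source_id -> bin index.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not peaks:
        return {}
    intensities = np.array([p.intensity for p in peaks])
    order = np.argsort(intensities, kind="stable")  # ascending
    chunks = np.array_split(order, n_bins)
    assignment: dict[str, int] = {}
    for bin_idx, chunk in enumerate(chunks, start=1):
        for i in chunk:
            assignment[peaks[int(i)].source_id] = bin_idx
    return assignment


def read_peaks(path: str | Path, factor: str | None = None) -> list[Peak]:
    """Read a BED5 peak file (chrom, start, end, name, score).

    The factor name defaults to the file stem; the score column, when
    present, is the tag intensity.  source_ids come from the name column or
    are synthesised as ``<factor>_<line index>``.
    """
    path = Path(path)
    if factor is None:
        factor = path.stem
    peaks: list[Peak] = []
    with open(path) as handle:
        idx = 0
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"{factor}_{idx}"
            score = float(fields[4]) if len(fields) > 4 else 0.0
            peaks.append(
                Peak(GenomicInterval(fields[0], start, end), factor=factor, intensity=score, source_id=name)
            )
            idx += 1
    return peaks


def write_clusters(clusters: list[Cluster], path: str | Path) -> None:
    """Write clusters as a BED-like table: chrom, start, end, size, factors, member ids."""
    with open(path, "w") as handle:
        handle.write("chrom\tstart\tend\tsize\tfactors\tmember_ids\n")
        for cl in clusters:
            factors = ",".join(sorted(cl.factors))
            ids = ",".join(p.source_id for p in cl.peaks)
            handle.write(
                f"{cl.region.chrom}\t{cl.region.start}\t{cl.region.end}\t{cl.size}\t{factors}\t{ids}\n"
            )
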