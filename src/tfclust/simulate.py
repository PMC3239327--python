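"""Synthetic genome generator with planted regulatory elements.

The generator builds a small multi-chromosome genome containing:

* non-overlapping genes with zero-inflated log-normal expression,
* planted regulatory elements of five classes — active promoters (at
  high-expression genes), silent promoters (at zero-expression genes),
  genic enhancers (gene bodies or 10-kb upstream windows), intergenic
  enhancers and intergenic transcript units (both at least 50 kb from any
  gene),
* per-element factor peaks drawn from class-specific composition
  probabilities (one Bernoulli draw per factor, with a floor of two peaks
  per element),
* per-class histone-mark / polymerase / open-chromatin domains with an
  optional dropout probability, and
* uniformly placed noise peaks over the mappable fraction of each
  chromosome.

Every non-noise peak traces to exactly one element through the ground-truth
manifest, so cluster construction, gene-context assignment, chromatin
classification and composition analysis all have recoverable targets.
Elements are spaced at least ``element_spacing`` bp apart (default 3,000 —
wider than the 2,000-bp peak extension) so distinct elements yield distinct
clusters, and enhancer-class elements are kept clear of every
transcription-mark footprint so their expected class is unambiguous.
Output is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .core import Genome, GenomicInterval, RegionSet, merge_overlapping, write_bed, write_chrom_sizes
from .clustering import Cluster, Peak
from .genes import Gene, classify_expression, write_expression, write_refgene

__all__ = [
    "ElementClass",
    "SyntheticConfig",
    "ElementRecord",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "write_manifest",
    "read_manifest",
    "match_clusters_to_elements",
    "element_recovery",
]


class ElementClass(str, Enum):
    ACTIVE_PROMOTER = "active_promoter"
    SILENT_PROMOTER = "silent_promoter"
    GENIC_ENHANCER = "genic_enhancer"
    INTERGENIC_ENHANCER = "intergenic_enhancer"
    INTERGENIC_TRANSCRIPT_UNIT = "intergenic_transcript_unit"


#: classes whose elements carry transcription signatures (H3K36me3/Pol II/III)
TRANSCRIPT_CLASSES = frozenset(
    {ElementClass.ACTIVE_PROMOTER, ElementClass.INTERGENIC_TRANSCRIPT_UNIT}
)

DEFAULT_FACTORS = (
    "CTCF", "Rad21", "SP1", "MYC", "MAX", "NFYA",
    "YY1", "EGR1", "JUN", "FOS", "GATA1", "TAL1",
)

# Per-class factor-composition probabilities: probability that an element of
# the class receives a peak for the factor.  Promoter classes favour
# promoter-type factors (SP1/MYC/MAX/NFYA/YY1/EGR1); enhancer classes favour
# AP-1 and erythroid factors (JUN/FOS/GATA1/TAL1) plus architectural
# CTCF/Rad21, echoing the compositional split the analysis is meant to
# detect.
DEFAULT_COMPOSITIONS: dict[ElementClass, dict[str, float]] = {
    ElementClass.ACTIVE_PROMOTER: {
        "CTCF": 0.15, "Rad21": 0.10, "SP1": 0.80, "MYC": 0.70, "MAX": 0.60,
        "NFYA": 0.60, "YY1": 0.50, "EGR1": 0.40, "JUN": 0.15, "FOS": 0.15,
        "GATA1": 0.20, "TAL1": 0.15,
    },
    ElementClass.SILENT_PROMOTER: {
        "CTCF": 0.50, "Rad21": 0.45, "SP1": 0.30, "MYC": 0.15, "MAX": 0.20,
        "NFYA": 0.15, "YY1": 0.30, "EGR1": 0.15, "JUN": 0.10, "FOS": 0.10,
        "GATA1": 0.15, "TAL1": 0.10,
    },
    ElementClass.GENIC_ENHANCER: {
        "CTCF": 0.40, "Rad21": 0.35, "SP1": 0.20, "MYC": 0.20, "MAX": 0.25,
        "NFYA": 0.10, "YY1": 0.15, "EGR1": 0.20, "JUN": 0.60, "FOS": 0.55,
        "GATA1": 0.60, "TAL1": 0.50,
    },
    ElementClass.INTERGENIC_ENHANCER: {
        "CTCF": 0.45, "Rad21": 0.40, "SP1": 0.15, "MYC": 0.15, "MAX": 0.20,
        "NFYA": 0.10, "YY1": 0.10, "EGR1": 0.15, "JUN": 0.65, "FOS": 0.60,
        "GATA1": 0.65, "TAL1": 0.55,
    },
    ElementClass.INTERGENIC_TRANSCRIPT_UNIT: {
        "CTCF": 0.30, "Rad21": 0.25, "SP1": 0.50, "MYC": 0.45, "MAX": 0.40,
        "NFYA": 0.30, "YY1": 0.40, "EGR1": 0.30, "JUN": 0.30, "FOS": 0.25,
        "GATA1": 0.30, "TAL1": 0.25,
    },
}

MARKS = (
    "H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K9ac",
    "H3K36me3", "H3K27me3", "PolII", "PolIII", "OCR",
)

# Per-class mark emission probabilities.  Signature marks that define the
# expected transcript/enhancer label are deterministic (probability 1.0) so
# zero-dropout runs are exactly recoverable; decoration marks are
# probabilistic.  Enhancer classes emit H3K4me1 at 0.9 and H3K27ac at 0.4.
DEFAULT_MARK_EMISSION: dict[ElementClass, dict[str, float]] = {
    ElementClass.ACTIVE_PROMOTER: {
        "H3K4me3": 1.0, "H3K4me2": 0.90, "H3K4me1": 0.50, "H3K27ac": 0.90,
        "H3K9ac": 0.85, "H3K36me3": 1.0, "H3K27me3": 0.02, "PolII": 0.90,
        "PolIII": 0.0, "OCR": 0.95,
    },
    ElementClass.SILENT_PROMOTER: {
        "H3K4me3": 0.50, "H3K4me2": 0.30, "H3K4me1": 0.30, "H3K27ac": 0.05,
        "H3K9ac": 0.05, "H3K36me3": 0.0, "H3K27me3": 0.85, "PolII": 0.0,
        "PolIII": 0.0, "OCR": 0.40,
    },
    ElementClass.GENIC_ENHANCER: {
        "H3K4me3": 0.10, "H3K4me2": 0.50, "H3K4me1": 0.90, "H3K27ac": 0.40,
        "H3K9ac": 0.20, "H3K36me3": 0.0, "H3K27me3": 0.05, "PolII": 0.0,
        "PolIII": 0.0, "OCR": 0.85,
    },
    ElementClass.INTERGENIC_ENHANCER: {
        "H3K4me3": 0.10, "H3K4me2": 0.50, "H3K4me1": 0.90, "H3K27ac": 0.40,
        "H3K9ac": 0.20, "H3K36me3": 0.0, "H3K27me3": 0.05, "PolII": 0.0,
        "PolIII": 0.0, "OCR": 0.85,
    },
    ElementClass.INTERGENIC_TRANSCRIPT_UNIT: {
        "H3K4me3": 0.80, "H3K4me2": 0.40, "H3K4me1": 0.30, "H3K27ac": 0.50,
        "H3K9ac": 0.40, "H3K36me3": 1.0, "H3K27me3": 0.0, "PolII": 0.70,
        "PolIII": 0.30, "OCR": 0.80,
    },
}

# Footprint margin (bp) added on each side of the element when a mark is
# emitted; H3K36me3 instead spans the host gene body for active promoters.
MARK_MARGIN: dict[str, int] = {
    "H3K4me1": 500, "H3K4me2": 500, "H3K4me3": 500, "H3K27ac": 500,
    "H3K9ac": 500, "H3K36me3": 0, "H3K27me3": 2000, "PolII": 1000,
    "PolIII": 200, "OCR": 100,
}

DEFAULT_ELEMENT_COUNTS: dict[ElementClass, int] = {
    ElementClass.ACTIVE_PROMOTER: 70,
    ElementClass.SILENT_PROMOTER: 50,
    ElementClass.GENIC_ENHANCER: 120,
    ElementClass.INTERGENIC_ENHANCER: 180,
    ElementClass.INTERGENIC_TRANSCRIPT_UNIT: 80,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; ``seed`` is mandatory.

    Defaults give two 10-Mb chromosomes, 240 genes, 500 planted elements and
    12 factors — big enough that per-class statistics are stable, small
    enough to simulate in seconds.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    n_genes: int = 240
    expression_zero_fraction: float = 0.35
    expression_lognormal_mu: float = 2.0
    expression_lognormal_sigma: float = 1.2
    element_counts: dict[ElementClass, int] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_COUNTS)
    )
    factors: tuple[str, ...] = DEFAULT_FACTORS
    compositions: dict[ElementClass, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPOSITIONS.items()}
    )
    mark_emission: dict[ElementClass, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARK_EMISSION.items()}
    )
    min_peaks_per_element: int = 2
    extra_peaks_poisson_mean: float = 0.0  # extra same-composition redraws; 0 = one Bernoulli sweep
    peak_length_range: tuple[int, int] = (150, 400)
    noise_peaks_per_mb: float = 5.0
    mark_dropout: float = 0.0
    mappability: float = 0.88
    element_spacing: int = 3000
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    intergenic_gene_clearance: int = 50_000

    def __post_init__(self) -> None:
        if not (0 <= self.expression_zero_fraction <= 1):
            raise ValueError("zero-inflation fraction must be in [0, 1]")
        if not (0 <= self.mark_dropout <= 1):
            raise ValueError("mark_dropout must be in [0, 1]")
        if self.noise_peaks_per_mb < 0:
            raise ValueError("noise rate must be >= 0")
        for counts in (self.element_counts,):
            for cls, n in counts.items():
                if n < 0:
                    raise ValueError(f"negative element count for {cls}")


@dataclass(frozen=True)
class ElementRecord:
    """Ground-truth record for one planted element."""

    element_id: str
    element_class: ElementClass
    chrom: str
    start: int
    end: int
    host_gene: str  # "" for intergenic classes
    expected_class: str  # transcript | enhancer
    expected_context: str  # promoter | gene | intergenic
    peak_ids: tuple[str, ...]
    marks: tuple[tuple[str, int, int], ...]  # (mark name, start, end)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class GroundTruth:
    """Complete manifest of the planted structure."""

    elements: list[ElementRecord]
    gene_classes: dict[str, str]  # gene id -> expression class value
    noise_peak_ids: tuple[str, ...]

    def peak_to_element(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for rec in self.elements:
            for pid in rec.peak_ids:
                mapping[pid] = rec.element_id
        return mapping


@dataclass
class SyntheticDataset:
    """In-memory bundle of everything :func:`generate` produced."""

    config: SyntheticConfig
    genome: Genome
    genes: list[Gene]
    peaks_by_factor: dict[str, list[Peak]]
    marks: dict[str, RegionSet]
    truth: GroundTruth

    @property
    def all_peaks(self) -> list[Peak]:
        return [p for peaks in self.peaks_by_factor.values() for p in peaks]

    def write(self, outdir: str | Path) -> None:
        """Emit chrom.sizes, gene/expression tables, peak and mark BED files
        and the ground-truth manifest under ``outdir``."""
        outdir = Path(outdir)
        (outdir / "peaks").mkdir(parents=True, exist_ok=True)
        (outdir / "marks").mkdir(parents=True, exist_ok=True)
        write_chrom_sizes(self.genome, outdir / "genome.chrom.sizes")
        write_refgene(self.genes, outdir / "genes.tsv")
        write_expression({g.id: g.expression for g in self.genes}, outdir / "expression.tsv")
        for factor, peaks in self.peaks_by_factor.items():
            with open(outdir / "peaks" / f"{factor}.bed", "w") as handle:
                for p in peaks:
                    iv = p.interval
                    handle.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.source_id}\t{p.intensity!r}\n"
                    )
        for mark, regions in self.marks.items():
            write_bed(regions, outdir / "marks" / f"{mark}.bed")
        write_manifest(self.truth, outdir / "manifest.tsv")


# ---------------------------------------------------------------------------
# placement helpers

class _OccupancyTracker:
    """Keeps planted elements apart by at least ``spacing`` bp."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self.trees: dict[str, IntervalTree] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(chrom)
        if tree is None:
            return True
        return not tree.overlaps(start - self.spacing, end + self.spacing)

    def add(self, chrom: str, start: int, end: int) -> None:
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end)


def _place_genes(config: SyntheticConfig, rng: np.random.Generator) -> list[Gene]:
    """Lay genes down sequentially in the proximal 55% of each chromosome.

    Inter-gene gaps of 15-35 kb leave room for the 10-kb upstream windows
    genic enhancers use, and keep neighbouring mark footprints apart.
    """
    chroms = list(config.chrom_lengths)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes % len(chroms)):
        per_chrom[i] += 1

    genes: list[Gene] = []
    gi = 0
    for chrom, n in zip(chroms, per_chrom):
        zone_end = int(0.55 * config.chrom_lengths[chrom])
        cursor = 50_000
        for _ in range(n):
            gap = int(rng.integers(15_000, 35_001))
            length = int(rng.integers(5_000, 20_001))
            start = cursor + gap
            end = start + length
            if end > zone_end:
                raise ValueError(
                    f"infeasible placement: {config.n_genes} genes do not fit "
                    f"the gene zone of chromosome {chrom}"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(3, 9))
            bounds = np.linspace(start, end, n_exons + 1).astype(int)
            exons = tuple(
                (int(bounds[k]), int(bounds[k] + max(50, (bounds[k + 1] - bounds[k]) // 3)))
                for k in range(n_exons)
            )
            genes.append(
                Gene(
                    id=f"G{gi:04d}", chrom=chrom, strand=strand,
                    tx_start=start, tx_end=end, exons=exons,
                )
            )
            gi += 1
            cursor = end
    return genes


def _assign_expression(genes: list[Gene], config: SyntheticConfig, rng: np.random.Generator) -> list[Gene]:
    out: list[Gene] = []
    for g in genes:
        if rng.random() < config.expression_zero_fraction:
            expr = 0.0
        else:
            expr = float(
                rng.lognormal(config.expression_lognormal_mu, config.expression_lognormal_sigma)
            )
        out.append(replace(g, expression=expr))
    return out


def _promoter_element(gene: Gene, config: SyntheticConfig, genome: Genome) -> GenomicInterval:
    up, down = config.promoter_upstream, config.promoter_downstream
    if gene.strand == "+":
        start, end = gene.tss - up, gene.tss + down
    else:
        start, end = gene.tss - down, gene.tss + up
    chrom_len = genome[gene.chrom]
    return GenomicInterval(gene.chrom, max(0, start), min(chrom_len, end))


def _genic_enhancer_site(
    gene: Gene,
    length: int,
    config: SyntheticConfig,
    occupancy: _OccupancyTracker,
    rng: np.random.Generator,
    margin: int = 1200,
) -> GenomicInterval | None:
    """A slot inside the gene body or 10-kb upstream window, clear of the
    promoter window by ``margin`` bp and of other elements by the global
    spacing.  Returns None when no free slot is found."""
    up, down = config.promoter_upstream, config.promoter_downstream
    if gene.strand == "+":
        body = (gene.tx_start + down + margin, gene.tx_end - length)
        upstream = (gene.tss - 10_000, gene.tss - up - margin - length)
    else:
        body = (gene.tx_start, gene.tx_end - down - margin - length)
        upstream = (gene.tss + up + margin, gene.tss + 10_000 - length)
    windows = [w for w in (body, upstream) if w[1] > w[0]]
    rng.shuffle(windows)
    for lo, hi in windows:
        for _ in range(10):
            start = int(rng.integers(lo, hi + 1))
            if occupancy.is_free(gene.chrom, start, start + length):
                return GenomicInterval(gene.chrom, start, start + length)
    return None


def _element_peaks(
    element_id: str,
    interval: GenomicInterval,
    composition: dict[str, float],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[Peak]:
    factors = list(config.factors)
    probs = np.array([composition.get(f, 0.0) for f in factors])
    chosen = [f for f, p in zip(factors, probs) if rng.random() < p]
    if len(chosen) < config.min_peaks_per_element:
        remaining = [f for f in factors if f not in chosen]
        weights = np.array([max(composition.get(f, 0.0), 1e-6) for f in remaining])
        extra = rng.choice(
            len(remaining),
            size=config.min_peaks_per_element - len(chosen),
            replace=False,
            p=weights / weights.sum(),
        )
        chosen += [remaining[int(i)] for i in np.atleast_1d(extra)]
    lo, hi = config.peak_length_range
    peaks: list[Peak] = []
    for k, factor in enumerate(f for f in factors if f in chosen):
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(interval.start, interval.end - length + 1))
        intensity = float(rng.lognormal(np.log(25.0), 0.8))
        peaks.append(
            Peak(
                interval=GenomicInterval(interval.chrom, start, start + length),
                factor=factor,
                intensity=intensity,
                source_id=f"{factor}:{element_id}:{k}",
            )
        )
    return peaks


def _element_marks(
    element_class: ElementClass,
    interval: GenomicInterval,
    host_gene: Gene | None,
    config: SyntheticConfig,
    genome: Genome,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    emitted: list[tuple[str, int, int]] = []
    emission = config.mark_emission[element_class]
    chrom_len = genome[interval.chrom]
    for mark in MARKS:
        p = emission.get(mark, 0.0)
        if p <= 0:
            continue
        if rng.random() >= p:
            continue
        if config.mark_dropout > 0 and rng.random() < config.mark_dropout:
            continue
        if mark == "H3K36me3" and element_class is ElementClass.ACTIVE_PROMOTER:
            assert host_gene is not None
            start, end = host_gene.tx_start, host_gene.tx_end
        else:
            margin = MARK_MARGIN[mark]
            start = max(0, interval.start - margin)
            end = min(chrom_len, interval.end + margin)
        emitted.append((mark, start, end))
    return emitted


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the synthetic genome, peaks, marks and ground truth.

    Deterministic given ``config.seed``.  Raises on infeasible placement
    (too many genes or elements for the genome size).
    """
    rng = np.random.default_rng(config.seed)
    genome = Genome(config.chrom_lengths)

    genes = _assign_expression(_place_genes(config, rng), config, rng)
    expr_classes = classify_expression(genes)
    genes_by_id = {g.id: g for g in genes}

    high = sorted(g.id for g in genes if expr_classes[g.id].value == "high")
    zero = sorted(g.id for g in genes if expr_classes[g.id].value == "zero")

    counts = config.element_counts
    n_active = counts.get(ElementClass.ACTIVE_PROMOTER, 0)
    n_silent = counts.get(ElementClass.SILENT_PROMOTER, 0)
    if n_active > len(high):
        raise ValueError(
            f"infeasible placement: {n_active} active promoters requested but "
            f"only {len(high)} high-expression genes available"
        )
    if n_silent > len(zero):
        raise ValueError(
            f"infeasible placement: {n_silent} silent promoters requested but "
            f"only {len(zero)} zero-expression genes available"
        )

    occupancy = _OccupancyTracker(config.element_spacing)
    elements: list[ElementRecord] = []
    peaks_by_factor: dict[str, list[Peak]] = {f: [] for f in config.factors}
    mark_intervals: dict[str, list[GenomicInterval]] = {m: [] for m in MARKS}
    eid = 0

    def plant(
        cls: ElementClass,
        interval: GenomicInterval,
        host: Gene | None,
        context: str,
    ) -> None:
        nonlocal eid
        element_id = f"E{eid:04d}"
        eid += 1
        peaks = _element_peaks(element_id, interval, config.compositions[cls], config, rng)
        marks = _element_marks(cls, interval, host, config, genome, rng)
        for p in peaks:
            peaks_by_factor[p.factor].append(p)
        for mark, s, e in marks:
            mark_intervals[mark].append(GenomicInterval(interval.chrom, s, e))
        elements.append(
            ElementRecord(
                element_id=element_id,
                element_class=cls,
                chrom=interval.chrom,
                start=interval.start,
                end=interval.end,
                host_gene=host.id if host is not None else "",
                expected_class="transcript" if cls in TRANSCRIPT_CLASSES else "enhancer",
                expected_context=context,
                peak_ids=tuple(p.source_id for p in peaks),
                marks=tuple(marks),
            )
        )
        occupancy.add(interval.chrom, interval.start, interval.end)

    # promoters at sampled high / zero expression genes
    active_hosts = [high[int(i)] for i in rng.choice(len(high), size=n_active, replace=False)]
    silent_hosts = [zero[int(i)] for i in rng.choice(len(zero), size=n_silent, replace=False)]
    for gid in active_hosts:
        gene = genes_by_id[gid]
        plant(ElementClass.ACTIVE_PROMOTER, _promoter_element(gene, config, genome), gene, "promoter")
    for gid in silent_hosts:
        gene = genes_by_id[gid]
        plant(ElementClass.SILENT_PROMOTER, _promoter_element(gene, config, genome), gene, "promoter")

    # genic enhancers at genes without transcription-mark footprints
    active_set = set(active_hosts)
    eligible = [g for g in genes if g.id not in active_set]
    n_genic = counts.get(ElementClass.GENIC_ENHANCER, 0)
    placed = 0
    attempts = 0
    while placed < n_genic:
        attempts += 1
        if attempts > 50 * max(n_genic, 1):
            raise ValueError("infeasible placement: could not site genic enhancers")
        gene = eligible[int(rng.integers(0, len(eligible)))]
        length = int(rng.integers(600, 1501))
        site = _genic_enhancer_site(gene, length, config, occupancy, rng)
        if site is None:
            continue
        plant(ElementClass.GENIC_ENHANCER, site, gene, "gene")
        placed += 1

    # intergenic elements in the distal zone, >= clearance from every gene
    intergenic_queue: list[ElementClass] = (
        [ElementClass.INTERGENIC_ENHANCER] * counts.get(ElementClass.INTERGENIC_ENHANCER, 0)
        + [ElementClass.INTERGENIC_TRANSCRIPT_UNIT]
        * counts.get(ElementClass.INTERGENIC_TRANSCRIPT_UNIT, 0)
    )
    rng.shuffle(intergenic_queue)
    chroms = list(config.chrom_lengths)
    gene_zone_end = {c: int(0.55 * config.chrom_lengths[c]) for c in chroms}
    for i, cls in enumerate(intergenic_queue):
        chrom = chroms[i % len(chroms)]
        zone_lo = gene_zone_end[chrom] + config.intergenic_gene_clearance
        zone_hi = config.chrom_lengths[chrom] - 10_000
        if cls is ElementClass.INTERGENIC_TRANSCRIPT_UNIT:
            length = int(rng.integers(1500, 3001))
        else:
            length = int(rng.integers(600, 1501))
        for attempt in range(200):
            start = int(rng.integers(zone_lo, zone_hi - length))
            if occupancy.is_free(chrom, start, start + length):
                plant(cls, GenomicInterval(chrom, start, start + length), None, "intergenic")
                break
        else:
            raise ValueError("infeasible placement: intergenic zone is saturated")

    # uniform noise peaks over the mappable span
    noise_ids: list[str] = []
    lo, hi = config.peak_length_range
    ni = 0
    for chrom, length in genome.items():
        n_noise = int(round(config.noise_peaks_per_mb * length / 1e6))
        for _ in range(n_noise):
            plen = int(rng.integers(lo, hi + 1))
            span = int(config.mappability * length)
            start = int(rng.integers(0, span - plen, endpoint=True))
            factor = config.factors[int(rng.integers(0, len(config.factors)))]
            intensity = float(rng.lognormal(np.log(8.0), 0.8))
            pid = f"{factor}:noise:{ni}"
            ni += 1
            peaks_by_factor[factor].append(
                Peak(GenomicInterval(chrom, start, start + plen), factor, intensity, pid)
            )
            noise_ids.append(pid)

    for factor in peaks_by_factor:
        peaks_by_factor[factor].sort(key=lambda p: (p.interval.chrom, p.interval.start, p.source_id))

    marks = {
        mark: merge_overlapping(RegionSet(label=mark, intervals=ivs))
        for mark, ivs in mark_intervals.items()
    }
    truth = GroundTruth(
        elements=elements,
        gene_classes={g.id: expr_classes[g.id].value for g in genes},
        noise_peak_ids=tuple(noise_ids),
    )
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        peaks_by_factor=peaks_by_factor,
        marks=marks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# manifest I/O

_MANIFEST_COLUMNS = (
    "record_type", "id", "class", "chrom", "start", "end",
    "host_gene", "expected_class", "expected_context", "peaks", "marks",
)


def write_manifest(truth: GroundTruth, path: str | Path) -> None:
    """Write the ground truth as a tab-separated manifest.

    Element rows carry coordinates, labels, peak ids and mark footprints;
    gene rows carry the expression class; one noise row lists noise peak
    ids.  Round-trips losslessly through :func:`read_manifest`.
    """
    with open(path, "w") as handle:
        handle.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for rec in truth.elements:
            marks = ";".join(f"{m}:{s}-{e}" for m, s, e in rec.marks)
            handle.write(
                "\t".join(
                    (
                        "element", rec.element_id, rec.element_class.value, rec.chrom,
                        str(rec.start), str(rec.end), rec.host_gene,
                        rec.expected_class, rec.expected_context,
                        ",".join(rec.peak_ids), marks,
                    )
                )
                + "\n"
            )
        for gid, cls in truth.gene_classes.items():
            handle.write("\t".join(("gene", gid, cls, "", "", "", "", "", "", "", "")) + "\n")
        if truth.noise_peak_ids:
            handle.write(
                "\t".join(
                    ("noise", "", "", "", "", "", "", "", "", ",".join(truth.noise_peak_ids), "")
                )
                + "\n"
            )


def read_manifest(path: str | Path) -> GroundTruth:
    elements: list[ElementRecord] = []
    gene_classes: dict[str, str] = {}
    noise_ids: tuple[str, ...] = ()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != _MANIFEST_COLUMNS:
            raise ValueError(f"unexpected manifest header in {path}")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            kind = fields[0]
            if kind == "element":
                marks = tuple(
                    (m.split(":")[0], int(m.split(":")[1].split("-")[0]), int(m.split(":")[1].split("-")[1]))
                    for m in fields[10].split(";")
                    if m
                )
                elements.append(
                    ElementRecord(
                        element_id=fields[1],
                        element_class=ElementClass(fields[2]),
                        chrom=fields[3],
                        start=int(fields[4]),
                        end=int(fields[5]),
                        host_gene=fields[6],
                        expected_class=fields[7],
                        expected_context=fields[8],
                        peak_ids=tuple(x for x in fields[9].split(",") if x),
                        marks=marks,
                    )
                )
            elif kind == "gene":
                gene_classes[fields[1]] = fields[2]
            elif kind == "noise":
                noise_ids = tuple(x for x in fields[9].split(",") if x)
    return GroundTruth(elements=elements, gene_classes=gene_classes, noise_peak_ids=noise_ids)


# ---------------------------------------------------------------------------
# recovery analysis against the manifest

def match_clusters_to_elements(
    clusters: list[Cluster], truth: GroundTruth
) -> dict[Cluster, str | None]:
    """Map each cluster to the planted element contributing most members.

    Clusters made purely of noise peaks map to None.
    """
    peak_map = truth.peak_to_element()
    matching: dict[Cluster, str | None] = {}
    for cl in clusters:
        votes: dict[str, int] = {}
        for p in cl.peaks:
            eid = peak_map.get(p.source_id)
            if eid is not None:
                votes[eid] = votes.get(eid, 0) + 1
        matching[cl] = max(sorted(votes), key=lambda e: votes[e]) if votes else None
    return matching


def element_recovery(clusters: list[Cluster], truth: GroundTruth, min_peaks: int = 2) -> float:
    """Fraction of multi-peak elements recovered by some cluster.

    An element is recovered when a single cluster holds at least
    ``min_peaks`` of its planted peaks.
    """
    eligible = [rec for rec in truth.elements if len(rec.peak_ids) >= min_peaks]
    if not eligible:
        return 0.0
    cluster_members: list[set[str]] = [{p.source_id for p in cl.peaks} for cl in clusters]
    recovered = 0
    for rec in eligible:
        ids = set(rec.peak_ids)
        if any(len(ids & members) >= min_peaks for members in cluster_members):
            recovered += 1
    return recovered / len(eligible)
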