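"""Gene annotation: nonredundant gene selection, expression classes,
promoter windows, cluster gene context and TSS-centred profiles.

Expression is consumed as a precomputed per-gene value (mean RNA-Seq tag
intensity over exons); no read counting happens here.  The transcription
start site (TSS) of a minus-strand gene is its ``tx_end`` coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .core import Genome, GenomicInterval
from .clustering import Cluster

__all__ = [
    "Gene",
    "ExpressionClass",
    "GeneContext",
    "ContextLabel",
    "read_refgene",
    "write_refgene",
    "read_expression",
    "write_expression",
    "select_nonredundant",
    "classify_expression",
    "promoter_interval",
    "upstream_interval",
    "assign_gene_context",
    "tss_profile",
]


@dataclass(frozen=True)
class Gene:
    """A transcript annotation record with an expression value."""

    id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    expression: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.id}: invalid transcript span")
        if self.expression < 0:
            raise ValueError(f"gene {self.id}: negative expression")
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"gene {self.id}: exon ({s},{e}) outside transcript")

    @property
    def tss(self) -> int:
        """txStart on the + strand, txEnd on the - strand."""
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end, self.strand)


class ExpressionClass(str, Enum):
    HIGH = "high"
    MEDIUM_LOW = "medium_low"
    ZERO = "zero"


class ContextLabel(str, Enum):
    PROMOTER = "promoter"
    GENE = "gene"
    INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GeneContext:
    """A cluster's relation to the gene annotation."""

    label: ContextLabel
    gene_id: str | None = None


def _exon_overlap_groups(genes: list[Gene]) -> list[list[int]]:
    """Transitive groups of genes sharing >=1 exon base on the same strand."""
    parent = list(range(len(genes)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    trees: dict[tuple[str, str], IntervalTree] = {}
    for gi, gene in enumerate(genes):
        key = (gene.chrom, gene.strand)
        tree = trees.setdefault(key, IntervalTree())
        for s, e in gene.exons:
            for hit in tree.overlap(s, e):
                union(gi, hit.data)
            tree.addi(s, e, gi)

    groups: dict[int, list[int]] = {}
    for gi in range(len(genes)):
        groups.setdefault(find(gi), []).append(gi)
    return list(groups.values())


def select_nonredundant(genes: list[Gene]) -> list[Gene]:
    """Collapse genes with same-strand overlapping exons to one per group.

    From each transitive overlap group the gene with the highest expression
    is kept; ties go to the longest transcript, then lexicographic id.
    Output order follows genomic position.
    """
    kept: list[Gene] = []
    for group in _exon_overlap_groups(genes):
        best = min(
            group,
            key=lambda gi: (
                -genes[gi].expression,
                -(genes[gi].tx_end - genes[gi].tx_start),
                genes[gi].id,
            ),
        )
        kept.append(genes[best])
    return sorted(kept, key=lambda g: (g.chrom, g.tx_start, g.tx_end, g.id))


def classify_expression(genes: list[Gene]) -> dict[str, ExpressionClass]:
    """Partition genes into high / medium_low / zero expression classes.

    The ``floor(n/3)`` genes with the highest (nonzero) expression are
    ``high``; genes with expression exactly 0 are ``zero``; everything else
    is ``medium_low``.  Ties at the tertile boundary resolve by descending
    expression then lexicographic id.
    """
    n = len(genes)
    k = n // 3
    ranked = sorted(genes, key=lambda g: (-g.expression, g.id))
    classes: dict[str, ExpressionClass] = {}
    high_ids = {g.id for g in ranked[:k] if g.expression > 0}
    for g in genes:
        if g.expression == 0:
            classes[g.id] = ExpressionClass.ZERO
        elif g.id in high_ids:
            classes[g.id] = ExpressionClass.HIGH
        else:
            classes[g.id] = ExpressionClass.MEDIUM_LOW
    return classes


def promoter_interval(
    gene: Gene,
    genome: Genome,
    upstream: int = 2000,
    downstream: int = 200,
) -> GenomicInterval:
    """Strand-oriented promoter window around the TSS, clamped to bounds.

    Plus strand: ``[TSS - upstream, TSS + downstream)``; minus strand is the
    mirror image.
    """
    t = gene.tss
    if gene.strand == "+":
        start, end = t - upstream, t + downstream
    else:
        start, end = t - downstream, t + upstream
    chrom_len = genome[gene.chrom]
    return GenomicInterval(gene.chrom, max(0, start), min(chrom_len, end), gene.strand)


def upstream_interval(gene: Gene, genome: Genome, upstream: int = 10000) -> GenomicInterval:
    """Strand-oriented window of ``upstream`` bp ending at the TSS."""
    t = gene.tss
    if gene.strand == "+":
        start, end = t - upstream, t
    else:
        start, end = t, t + upstream
    chrom_len = genome[gene.chrom]
    return GenomicInterval(gene.chrom, max(0, start), min(chrom_len, end), gene.strand)


class GeneContextAssigner:
    """Precomputed promoter/gene/upstream indexes for context assignment.

    Promoter context wins over gene context; gene context means overlap with
    a gene body or its 10-kb upstream window outside the promoter; otherwise
    the cluster is intergenic.  When several genes qualify with the winning
    label, the one whose TSS is nearest the cluster midpoint is assigned.
    """

    def __init__(
        self,
        genes: list[Gene],
        genome: Genome,
        upstream_gene_limit: int = 10000,
        promoter_upstream: int = 2000,
        promoter_downstream: int = 200,
    ):
        self.genes = genes
        self._promoters: dict[str, IntervalTree] = {}
        self._gene_zones: dict[str, IntervalTree] = {}
        for gi, gene in enumerate(genes):
            prom = promoter_interval(gene, genome, promoter_upstream, promoter_downstream)
            self._promoters.setdefault(gene.chrom, IntervalTree()).addi(prom.start, prom.end, gi)
            zone_tree = self._gene_zones.setdefault(gene.chrom, IntervalTree())
            zone_tree.addi(gene.tx_start, gene.tx_end, gi)
            up = upstream_interval(gene, genome, upstream_gene_limit)
            zone_tree.addi(up.start, up.end, gi)

    def assign(self, cluster: Cluster) -> GeneContext:
        region = cluster.region
        mid = region.midpoint

        def nearest(gene_ids: set[int]) -> str:
            return min(
                gene_ids,
                key=lambda gi: (abs(self.genes[gi].tss - mid), self.genes[gi].id),
            )

        prom_tree = self._promoters.get(region.chrom)
        if prom_tree is not None:
            hits = {h.data for h in prom_tree.overlap(region.start, region.end)}
            if hits:
                return GeneContext(ContextLabel.PROMOTER, self.genes[nearest(hits)].id)
        zone_tree = self._gene_zones.get(region.chrom)
        if zone_tree is not None:
            hits = {h.data for h in zone_tree.overlap(region.start, region.end)}
            if hits:
                return GeneContext(ContextLabel.GENE, self.genes[nearest(hits)].id)
        return GeneContext(ContextLabel.INTERGENIC)


def assign_gene_context(
    cluster: Cluster,
    genes: list[Gene],
    genome: Genome,
    upstream_gene_limit: int = 10000,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 200,
) -> GeneContext:
    """Assign one cluster a promoter / gene / intergenic context.

    Convenience wrapper; batch callers should build a
    :class:`GeneContextAssigner` once.
    """
    assigner = GeneContextAssigner(
        genes, genome, upstream_gene_limit, promoter_upstream, promoter_downstream
    )
    return assigner.assign(cluster)


def tss_profile(
    regions: list[GenomicInterval],
    genes: list[Gene],
    window: int,
    bin: int = 200,
) -> np.ndarray:
    """Histogram of region midpoints by signed distance to gene TSSs.

    Distances are strand-oriented (upstream negative) and binned in ``bin``-bp
    intervals over ``[-window, window)``; the returned vector has
    ``2*window/bin`` counts.  A region near several TSSs contributes to each.
    """
    if window % bin != 0:
        raise ValueError("window must be a multiple of bin")
    n_bins = 2 * window // bin
    counts = np.zeros(n_bins, dtype=int)
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.strand))
    for iv in regions:
        mid = iv.midpoint
        for tss, strand in tss_by_chrom.get(iv.chrom, []):
            d = mid - tss if strand == "+" else tss - mid
            if -window <= d < window:
                counts[(d + window) // bin] += 1
    return counts


# ---------------------------------------------------------------------------
# refGene-like I/O

def read_refgene(path: str | Path, expression: dict[str, float] | None = None) -> list[Gene]:
    """Read a refGene-like table.

    Columns (tab-separated): id, chrom, strand, txStart, txEnd, exonCount,
    exonStarts, exonEnds (comma-separated lists, trailing comma tolerated),
    optionally a 9th expression column.  A separate ``expression`` mapping
    overrides the column.
    """
    genes: list[Gene] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >=8 columns")
            gid, chrom, strand = fields[0], fields[1], fields[2]
            tx_start, tx_end = int(fields[3]), int(fields[4])
            n_exons = int(fields[5])
            starts = [int(x) for x in fields[6].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[7].rstrip(",").split(",") if x]
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ValueError(f"{path}:{lineno}: exon count mismatch")
            expr = 0.0
            if expression is not None and gid in expression:
                expr = expression[gid]
            elif len(fields) > 8 and fields[8]:
                expr = float(fields[8])
            genes.append(
                Gene(
                    id=gid,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=tuple(zip(starts, ends)),
                    expression=expr,
                )
            )
    return genes


def write_refgene(genes: list[Gene], path: str | Path, with_expression: bool = False) -> None:
    with open(path, "w") as handle:
        for g in genes:
            starts = ",".join(str(s) for s, _ in g.exons) + ","
            ends = ",".join(str(e) for _, e in g.exons) + ","
            row = [g.id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end), str(len(g.exons)), starts, ends]
            if with_expression:
                row.append(repr(g.expression))
            handle.write("\t".join(row) + "\n")


def read_expression(path: str | Path) -> dict[str, float]:
    """Read a two-column (gene id, mean exon tag intensity) table."""
    values: dict[str, float] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            values[fields[0]] = float(fields[1])
    return values


def write_expression(values: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as handle:
        for gid, v in values.items():
            handle.write(f"{gid}\t{v!r}\n")
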