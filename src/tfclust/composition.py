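"""Factor-composition vectors, their correlations, and coverage curves.

The composition of a cluster group is the vector of per-factor occupancy
fractions (share of clusters in the group containing at least one peak of
each factor).  Groups are compared by Pearson's r between their vectors.
Coverage curves measure how the fraction of target regions touched by
clustered peaks grows as factors are added in random order, averaged over
many shuffled orders.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import RegionSet, build_interval_index
from .clustering import Cluster, Peak

__all__ = [
    "CompositionVector",
    "CoverageCurve",
    "composition_vector",
    "pearson_r",
    "coverage_curve",
]


@dataclass(frozen=True)
class CompositionVector:
    """Per-factor occupancy fractions for one group of clusters.

    ``empty_group`` flags the degenerate 0-vector produced by an empty
    cluster group; correlations with such a vector are refused upstream.
    """

    factors: tuple[str, ...]
    values: tuple[float, ...]
    empty_group: bool = False

    def __post_init__(self) -> None:
        if len(self.factors) != len(self.values):
            raise ValueError("factor/value length mismatch")
        for v in self.values:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fraction {v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __getitem__(self, factor: str) -> float:
        return self.values[self.factors.index(factor)]


def composition_vector(clusters: list[Cluster], factors: list[str]) -> CompositionVector:
    """Fraction of clusters containing each factor, in the given order."""
    if not factors:
        raise ValueError("factor list must be nonempty")
    if not clusters:
        return CompositionVector(tuple(factors), tuple(0.0 for _ in factors), empty_group=True)
    counts = {f: 0 for f in factors}
    for cl in clusters:
        present = cl.factors
        for f in factors:
            if f in present:
                counts[f] += 1
    n = len(clusters)
    return CompositionVector(tuple(factors), tuple(counts[f] / n for f in factors))


def pearson_r(a: CompositionVector, b: CompositionVector) -> float:
    """Pearson product-moment correlation between two composition vectors.

    Requires identical factor ordering, length >= 2 and non-constant
    vectors; a constant vector has undefined correlation and raises rather
    than silently returning 0.
    """
    if a.factors != b.factors:
        raise ValueError("composition vectors are over different factor orderings")
    if len(a.factors) < 2:
        raise ValueError("need at least 2 factors for a correlation")
    x, y = a.as_array(), b.as_array()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant composition vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CoverageCurve:
    """Mean covered fraction of targets after adding k factors, k=0..n.

    ``values[k]`` is the mean over shuffled factor orders of the fraction of
    target regions overlapped by at least one qualifying peak of the first k
    factors; nondecreasing with values[0] = 0.
    """

    factors: tuple[str, ...]
    values: tuple[float, ...]
    n_orders: int
    seed: int | None = None
    include_singletons: bool = False

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def _covered_targets_by_factor(
    targets: RegionSet,
    peaks_by_factor: dict[str, list[Peak]],
) -> dict[str, frozenset[int]]:
    index = build_interval_index(targets)
    covered: dict[str, frozenset[int]] = {}
    for factor, peaks in peaks_by_factor.items():
        hit: set[int] = set()
        for p in peaks:
            tree = index.get(p.interval.chrom)
            if tree is None:
                continue
            for node in tree.overlap(p.interval.start, p.interval.end):
                hit.add(node.data)
        covered[factor] = frozenset(hit)
    return covered


def coverage_curve(
    targets: RegionSet,
    peaks_by_factor: dict[str, list[Peak]],
    n_orders: int = 100,
    seed: int | np.random.Generator = 0,
    include_singletons: bool = False,
    clusters: list[Cluster] | None = None,
    exhaustive: bool = False,
) -> CoverageCurve:
    """Coverage saturation curve over randomly ordered factor additions.

    A target counts as covered by the first k factors of an order when at
    least one qualifying peak of those factors overlaps it.  Qualifying
    peaks are the member peaks of ``clusters`` (cluster membership computed
    once on the full factor set, not re-clustered per prefix) unless
    ``include_singletons`` is set, in which case every peak qualifies.  The
    curve is the mean over ``n_orders`` uniformly shuffled orders — or over
    every permutation when ``exhaustive`` is set (feasible for small factor
    panels only).  Deterministic given the seed.
    """
    if len(targets) == 0:
        raise ValueError("target set is empty")
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")

    factors = sorted(peaks_by_factor)
    if include_singletons:
        qualifying = peaks_by_factor
    else:
        if clusters is None:
            raise ValueError("clusters are required unless include_singletons is set")
        member_ids = {p.source_id for cl in clusters for p in cl.peaks}
        qualifying = {
            f: [p for p in peaks if p.source_id in member_ids]
            for f, peaks in peaks_by_factor.items()
        }
    covered = _covered_targets_by_factor(targets, qualifying)
    n_targets = len(targets)

    if exhaustive:
        orders = list(itertools.permutations(range(len(factors))))
        if math.factorial(len(factors)) > 50000:
            raise ValueError("too many factors for exhaustive order enumeration")
        order_arrays = [np.array(o, dtype=int) for o in orders]
        n_used = len(order_arrays)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order_arrays = [rng.permutation(len(factors)) for _ in range(n_orders)]
        n_used = n_orders

    totals = np.zeros(len(factors) + 1, dtype=float)
    for order in order_arrays:
        seen: set[int] = set()
        for k, fi in enumerate(order, start=1):
            seen |= covered[factors[fi]]
            totals[k] += len(seen) / n_targets
    values = totals / n_used
    values[0] = 0.0
    return CoverageCurve(
        factors=tuple(factors),
        values=tuple(float(v) for v in values),
        n_orders=n_used,
        seed=seed if isinstance(seed, int) else None,
        include_singletons=include_singletons,
    )
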