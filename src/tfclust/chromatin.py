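"""Transcript vs enhancer classification of clusters from chromatin marks.

A cluster is a transcript cluster when it overlaps H3K36me3 (elongation
mark), Pol II, Pol III, or an H3K4me3 domain that itself touches H3K36me3 or
Pol II; a cluster lacking all of those signatures is an enhancer cluster.
Classification consults full-length mark domains; overlap statistics use the
5-kb split variants (broad domains would otherwise dominate counts).
CTCF/Rad21-only clusters, which reflect chromatin architecture rather than
local regulation, are excluded from classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import pandas as pd

from .core import RegionSet, build_interval_index, merge_overlapping, overlap_fraction, split_to_max_length
from .clustering import Cluster
from .genes import ContextLabel, ExpressionClass, GeneContext

__all__ = [
    "MarkLibrary",
    "ClusterClass",
    "Provenance",
    "classify_clusters",
    "cross_tabulate",
    "enhancer_marker_overlap",
    "redundancy_ratio",
    "DEFAULT_EXCLUDE_FACTORS",
]

DEFAULT_EXCLUDE_FACTORS = frozenset({"CTCF", "Rad21"})

H3K36ME3 = "H3K36me3"
H3K4ME3 = "H3K4me3"
POL2 = "PolII"
POL3 = "PolIII"


class Provenance(str, Enum):
    """Which transcription rule fired, in fixed evaluation order."""

    H3K36ME3 = "H3K36me3"
    POL2 = "PolII"
    H3K4ME3_LINKED = "H3K4me3-linked"
    POL3 = "PolIII"
    NONE = "none"


@dataclass(frozen=True)
class ClusterClass:
    label: str  # "transcript" | "enhancer"
    provenance: Provenance


class MarkLibrary:
    """Full-length and 5-kb split variants of every mark track.

    Split regions are used for overlap statistics; full-length domains only
    for the transcript-cluster rules.
    """

    def __init__(self, tracks: Mapping[str, RegionSet], max_split_length: int = 5000):
        self.full: dict[str, RegionSet] = {
            name: merge_overlapping(track) for name, track in tracks.items()
        }
        self.split: dict[str, RegionSet] = {
            name: split_to_max_length(track, max_split_length)
            for name, track in self.full.items()
        }

    def __contains__(self, name: str) -> bool:
        return name in self.full

    def marks(self) -> list[str]:
        return list(self.full)


def classify_clusters(
    clusters: list[Cluster],
    marks: MarkLibrary,
    exclude_factors: frozenset[str] | set[str] = DEFAULT_EXCLUDE_FACTORS,
) -> dict[Cluster, ClusterClass]:
    """Classify clusters as transcript or enhancer.

    Clusters whose member factors all belong to ``exclude_factors`` are
    dropped from the result (mixed clusters keep all their peaks and are
    classified normally).  Rules, in provenance order: overlap with
    H3K36me3; overlap with Pol II; overlap with an H3K4me3 full-length
    domain that itself overlaps H3K36me3 or Pol II; overlap with Pol III
    (when the track is available).  A cluster matching no rule is an
    enhancer.  The order only fixes provenance; the class itself is
    order-independent.
    """
    for required in (H3K36ME3, H3K4ME3, POL2):
        if required not in marks:
            raise KeyError(f"mark library is missing required track {required!r}")

    k36_index = build_interval_index(marks.full[H3K36ME3])
    pol2_index = build_interval_index(marks.full[POL2])
    pol3_index = build_interval_index(marks.full[POL3]) if POL3 in marks else None

    def hits(index, region) -> bool:
        tree = index.get(region.chrom)
        return tree is not None and tree.overlaps(region.start, region.end)

    # H3K4me3 domains linked to transcription: full-length on both sides
    linked_k4me3 = RegionSet(
        label="H3K4me3-linked",
        intervals=[
            iv
            for iv in marks.full[H3K4ME3]
            if hits(k36_index, iv) or hits(pol2_index, iv)
        ],
    )
    linked_index = build_interval_index(linked_k4me3)

    result: dict[Cluster, ClusterClass] = {}
    for cl in clusters:
        if cl.factors and cl.factors <= frozenset(exclude_factors):
            continue
        region = cl.region
        if hits(k36_index, region):
            cc = ClusterClass("transcript", Provenance.H3K36ME3)
        elif hits(pol2_index, region):
            cc = ClusterClass("transcript", Provenance.POL2)
        elif hits(linked_index, region):
            cc = ClusterClass("transcript", Provenance.H3K4ME3_LINKED)
        elif pol3_index is not None and hits(pol3_index, region):
            cc = ClusterClass("transcript", Provenance.POL3)
        else:
            cc = ClusterClass("enhancer", Provenance.NONE)
        result[cl] = cc
    return result


def cross_tabulate(
    classes: Mapping[Cluster, ClusterClass],
    contexts: Mapping[Cluster, GeneContext],
    expr_classes: Mapping[str, ExpressionClass],
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate cluster class against annotation and expression.

    Returns two tables: ``by_annotation`` counts (transcript, enhancer) x
    (inside, outside) where inside means a promoter or gene context, and
    ``by_expression`` counts cluster class against the expression class of
    the assigned gene (clusters without an assigned gene are omitted from
    the second table).
    """
    class_labels = ["transcript", "enhancer"]
    by_annot = pd.DataFrame(0, index=class_labels, columns=["inside", "outside"])
    expr_labels = [e.value for e in ExpressionClass]
    by_expr = pd.DataFrame(0, index=class_labels, columns=expr_labels)
    for cl, cc in classes.items():
        ctx = contexts.get(cl)
        if ctx is None:
            continue
        inside = "inside" if ctx.label in (ContextLabel.PROMOTER, ContextLabel.GENE) else "outside"
        by_annot.loc[cc.label, inside] += 1
        if ctx.gene_id is not None and ctx.gene_id in expr_classes:
            by_expr.loc[cc.label, expr_classes[ctx.gene_id].value] += 1
    return {"by_annotation": by_annot, "by_expression": by_expr}


def enhancer_marker_overlap(
    enhancer_clusters: list[Cluster],
    marks: MarkLibrary,
    markers: list[str] | None = None,
) -> dict[str, float]:
    """Fraction of enhancer clusters overlapping each candidate marker.

    Callers should pass enhancer clusters restricted to intergenic context.
    Overlap statistics use the split (<=5 kb) mark regions.
    """
    if markers is None:
        markers = marks.marks()
    regions = [cl.region for cl in enhancer_clusters]
    return {m: overlap_fraction(regions, marks.split[m]) for m in markers if m in marks}


def redundancy_ratio(mark: RegionSet, clusters: list[Cluster]) -> float:
    """Ratio of total mark regions to mark regions occupied by a cluster.

    A region is occupied when it overlaps at least one cluster.  Returns 0
    when no region is occupied (sentinel for an uninformative mark).
    """
    if not mark.merged:
        mark = merge_overlapping(mark)
    index = build_interval_index(cl.region for cl in clusters)
    occupied = 0
    for iv in mark:
        tree = index.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            occupied += 1
    if occupied == 0:
        return 0.0
    return len(mark.intervals) / occupied
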