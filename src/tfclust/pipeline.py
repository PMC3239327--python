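"""End-to-end orchestration of the cluster analysis.

``run`` wires the stages together on a directory of input tracks: cluster
construction and the shuffle null, mark-overlap tables, gene-context
assignment with TSS profiles, factor-composition correlations over the six
promoter/gene cluster groups, transcript/enhancer classification with
cross-tabulations, enhancer-marker overlaps, coverage saturation curves and
mark redundancy ratios.  All randomness flows from one seed; the run log
records every parameter and per-stage counts, so the conservation
invariants are checkable from the log alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    Genome,
    RegionSet,
    merge_overlapping,
    merge_within_gap,
    overlap_fraction,
    read_bed,
    read_chrom_sizes,
)
from .clustering import (
    Cluster,
    ClusterConfig,
    Peak,
    build_clusters,
    bin_peaks_by_intensity,
    cluster_size_histogram,
    mean_length_by_size,
    read_peaks,
    shuffle_peaks,
    write_clusters,
)
from .genes import (
    ContextLabel,
    ExpressionClass,
    GeneContextAssigner,
    classify_expression,
    promoter_interval,
    read_expression,
    read_refgene,
    select_nonredundant,
    tss_profile,
)
from .chromatin import (
    DEFAULT_EXCLUDE_FACTORS,
    MarkLibrary,
    classify_clusters,
    cross_tabulate,
    enhancer_marker_overlap,
    redundancy_ratio,
)
from .composition import composition_vector, coverage_curve, pearson_r

__all__ = ["RunConfig", "run"]

H3K4ME_MARKS = ("H3K4me1", "H3K4me2", "H3K4me3")


@dataclass
class RunConfig:
    """Inputs and parameters of a full analysis run.

    Numeric defaults are the study constants: 2,000-bp peak extension, size
    limit 2, mappability 0.88, -2,000/+200 promoters, 10-kb upstream gene
    windows, 5-kb mark splitting, 600-bp OCR merging, 100 coverage orders,
    20 intensity bins, CTCF/Rad21 excluded from classification.
    """

    data_dir: str
    outdir: str
    seed: int
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    upstream_gene_limit: int = 10000
    domain_max_length: int = 5000
    ocr_merge_gap: int = 600
    n_coverage_orders: int = 100
    n_intensity_bins: int = 20
    exclude_factors: tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDE_FACTORS))
    tss_profile_window: int = 5000
    tss_profile_bin: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        raw.update(overrides)
        cluster_raw = raw.pop("cluster", {})
        cfg = cls(**raw)
        if cluster_raw:
            cfg.cluster = ClusterConfig(**cluster_raw)
        return cfg


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def _load_inputs(config: RunConfig):
    data = Path(config.data_dir)
    genome = read_chrom_sizes(data / "genome.chrom.sizes")
    expression = None
    if (data / "expression.tsv").exists():
        expression = read_expression(data / "expression.tsv")
    genes = read_refgene(data / "genes.tsv", expression=expression)
    peaks_by_factor = {
        p.stem: read_peaks(p) for p in sorted((data / "peaks").glob("*.bed"))
    }
    marks = {p.stem: read_bed(p) for p in sorted((data / "marks").glob("*.bed"))}
    return genome, genes, peaks_by_factor, marks


def _composition_groups(
    clusters: list[Cluster],
    contexts,
    expr_classes,
    k4me_union: RegionSet,
) -> dict[str, list[Cluster]]:
    """The six cluster groups compared in the composition analysis.

    prom-h / prom-z: promoter clusters of transcribed (high) / silent
    genes; gene-pos / gene-neg: gene clusters overlapping / not overlapping
    any H3K4me region, each split by the assigned gene's expression class.
    """
    from .core import build_interval_index

    k4_index = build_interval_index(k4me_union)

    def touches_k4(cl: Cluster) -> bool:
        tree = k4_index.get(cl.region.chrom)
        return tree is not None and tree.overlaps(cl.region.start, cl.region.end)

    groups: dict[str, list[Cluster]] = {
        "prom-h": [], "prom-z": [],
        "gene-pos-h": [], "gene-pos-z": [],
        "gene-neg-h": [], "gene-neg-z": [],
    }
    for cl in clusters:
        ctx = contexts[cl]
        if ctx.gene_id is None:
            continue
        expr = expr_classes.get(ctx.gene_id)
        if expr is ExpressionClass.HIGH:
            suffix = "h"
        elif expr is ExpressionClass.ZERO:
            suffix = "z"
        else:
            continue
        if ctx.label is ContextLabel.PROMOTER:
            groups[f"prom-{suffix}"].append(cl)
        elif ctx.label is ContextLabel.GENE:
            key = "gene-pos" if touches_k4(cl) else "gene-neg"
            groups[f"{key}-{suffix}"].append(cl)
    return groups


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run log as a dict.

    Writes tab-separated tables for every stage under ``config.outdir``
    plus ``run_log.json``.  Any stage failure raises with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            **{k: v for k, v in asdict(config).items() if k != "cluster"},
            "cluster": asdict(config.cluster),
        },
        "stages": {},
    }
    stage = "load"
    try:
        genome, genes_all, peaks_by_factor, mark_tracks = _load_inputs(config)
        all_peaks: list[Peak] = [p for ps in peaks_by_factor.values() for p in ps]
        log["stages"][stage] = {
            "factors": len(peaks_by_factor),
            "peaks": len(all_peaks),
            "genes": len(genes_all),
            "marks": sorted(mark_tracks),
        }

        # --- clusters and the shuffle null ---------------------------------
        stage = "cluster"
        clusters, singletons = build_clusters(all_peaks, config.cluster, genome)
        shuffled = shuffle_peaks(
            all_peaks, genome, config.cluster.mappability, seed=config.seed
        )
        shuf_clusters, shuf_singletons = build_clusters(shuffled, config.cluster, genome)
        write_clusters(clusters, outdir / "clusters.tsv")
        write_clusters(singletons, outdir / "singletons.tsv")
        hist = cluster_size_histogram(clusters, singletons)
        shuf_hist = cluster_size_histogram(shuf_clusters, shuf_singletons)
        lengths = mean_length_by_size(clusters, singletons)
        shuf_lengths = mean_length_by_size(shuf_clusters, shuf_singletons)
        sizes = sorted(set(hist) | set(shuf_hist))
        null_table = pd.DataFrame(
            {
                "size": sizes,
                "real_count": [hist.get(s, 0) for s in sizes],
                "shuffled_count": [shuf_hist.get(s, 0) for s in sizes],
                "real_mean_length": [lengths.get(s, float("nan")) for s in sizes],
                "shuffled_mean_length": [shuf_lengths.get(s, float("nan")) for s in sizes],
            }
        )
        _write_tsv(null_table, outdir / "cluster_null_comparison.tsv")
        log["stages"][stage] = {
            "clusters": len(clusters),
            "singletons": len(singletons),
            "regions": len(clusters) + len(singletons),
            "shuffled_clusters": len(shuf_clusters),
            "shuffled_regions": len(shuf_clusters) + len(shuf_singletons),
        }

        # --- intensity bins -------------------------------------------------
        stage = "intensity_bins"
        singleton_ids = {p.source_id for cl in singletons for p in cl.peaks}
        rows = []
        for factor, peaks in peaks_by_factor.items():
            bins = bin_peaks_by_intensity(peaks, config.n_intensity_bins)
            for p in peaks:
                rows.append(
                    (factor, p.source_id, bins[p.source_id], p.source_id in singleton_ids)
                )
        bin_table = pd.DataFrame(rows, columns=["factor", "peak_id", "bin", "singleton"])
        _write_tsv(bin_table, outdir / "intensity_bins.tsv")
        log["stages"][stage] = {"binned_peaks": len(bin_table)}

        # --- mark overlap (with and without excluded factors) ---------------
        stage = "mark_overlap"
        marks = MarkLibrary(mark_tracks, config.domain_max_length)
        k4me_union = merge_overlapping(
            RegionSet(
                "H3K4me",
                [iv for m in H3K4ME_MARKS if m in marks.split for iv in marks.split[m]],
            )
        )
        overlap_tracks: dict[str, RegionSet] = dict(marks.split)
        overlap_tracks["H3K4me"] = k4me_union
        if "OCR" in mark_tracks:
            overlap_tracks["OCR_merged600"] = merge_within_gap(
                mark_tracks["OCR"], config.ocr_merge_gap
            )
        excluded = set(config.exclude_factors)
        retained_peaks = [p for p in all_peaks if p.factor not in excluded]
        clusters_noex, _ = build_clusters(retained_peaks, config.cluster, genome)
        regions_all = [cl.region for cl in clusters]
        regions_noex = [cl.region for cl in clusters_noex]
        overlap_table = pd.DataFrame(
            {
                "mark": list(overlap_tracks),
                "fraction_all": [
                    overlap_fraction(regions_all, t) for t in overlap_tracks.values()
                ],
                "fraction_excluding": [
                    overlap_fraction(regions_noex, t) for t in overlap_tracks.values()
                ],
            }
        )
        _write_tsv(overlap_table, outdir / "mark_overlap.tsv")
        log["stages"][stage] = {
            "tracks": len(overlap_tracks),
            "clusters_excluding": len(clusters_noex),
        }

        # --- gene context and TSS profiles ----------------------------------
        stage = "gene_context"
        genes = select_nonredundant(genes_all)
        expr_classes = classify_expression(genes)
        assigner = GeneContextAssigner(
            genes,
            genome,
            config.upstream_gene_limit,
            config.promoter_upstream,
            config.promoter_downstream,
        )
        contexts = {cl: assigner.assign(cl) for cl in clusters}
        ctx_table = pd.DataFrame(
            [
                (
                    cl.region.chrom, cl.region.start, cl.region.end, cl.size,
                    contexts[cl].label.value, contexts[cl].gene_id or "",
                )
                for cl in clusters
            ],
            columns=["chrom", "start", "end", "size", "context", "gene_id"],
        )
        _write_tsv(ctx_table, outdir / "gene_context.tsv")
        regions = [cl.region for cl in clusters]
        profiles = {}
        for label in ("high", "zero"):
            subset = [g for g in genes if expr_classes[g.id].value == label]
            profiles[label] = tss_profile(
                regions, subset, config.tss_profile_window, config.tss_profile_bin
            )
        offsets = np.arange(
            -config.tss_profile_window, config.tss_profile_window, config.tss_profile_bin
        )
        profile_table = pd.DataFrame({"offset": offsets, **profiles})
        _write_tsv(profile_table, outdir / "tss_profiles.tsv")
        log["stages"][stage] = {
            "nonredundant_genes": len(genes),
            "contexts": {
                lbl.value: sum(1 for c in contexts.values() if c.label is lbl)
                for lbl in ContextLabel
            },
        }

        # --- composition correlations ---------------------------------------
        stage = "composition"
        factor_order = sorted(peaks_by_factor)
        groups = _composition_groups(clusters, contexts, expr_classes, k4me_union)
        vectors = {name: composition_vector(cls, factor_order) for name, cls in groups.items()}
        comp_table = pd.DataFrame(
            {name: vec.values for name, vec in vectors.items()}, index=factor_order
        )
        _write_tsv(comp_table, outdir / "composition_vectors.tsv", index_label="factor")
        names = list(vectors)
        corr = pd.DataFrame(index=names, columns=names, dtype=float)
        for a in names:
            for b in names:
                try:
                    corr.loc[a, b] = pearson_r(vectors[a], vectors[b])
                except ValueError:
                    corr.loc[a, b] = float("nan")
        _write_tsv(corr, outdir / "composition_correlations.tsv", index_label="group")
        log["stages"][stage] = {name: len(cls) for name, cls in groups.items()}

        # --- transcript/enhancer classification -----------------------------
        stage = "classify"
        classes = classify_clusters(clusters, marks, excluded)
        class_table = pd.DataFrame(
            [
                (
                    cl.region.chrom, cl.region.start, cl.region.end, cl.size,
                    cc.label, cc.provenance.value,
                )
                for cl, cc in classes.items()
            ],
            columns=["chrom", "start", "end", "size", "class", "provenance"],
        )
        _write_tsv(class_table, outdir / "classification.tsv")
        tables = cross_tabulate(classes, contexts, expr_classes)
        _write_tsv(tables["by_annotation"], outdir / "crosstab_annotation.tsv", index_label="class")
        _write_tsv(tables["by_expression"], outdir / "crosstab_expression.tsv", index_label="class")
        log["stages"][stage] = {
            "classified": len(classes),
            "transcript": sum(1 for c in classes.values() if c.label == "transcript"),
            "enhancer": sum(1 for c in classes.values() if c.label == "enhancer"),
        }

        # --- enhancer marker overlap ----------------------------------------
        stage = "enhancer_markers"
        intergenic_enhancers = [
            cl
            for cl, cc in classes.items()
            if cc.label == "enhancer" and contexts[cl].label is ContextLabel.INTERGENIC
        ]
        marker_overlap = enhancer_marker_overlap(intergenic_enhancers, marks)
        marker_table = pd.DataFrame(
            sorted(marker_overlap.items()), columns=["marker", "fraction"]
        )
        _write_tsv(marker_table, outdir / "enhancer_marker_overlap.tsv")
        log["stages"][stage] = {"intergenic_enhancers": len(intergenic_enhancers)}

        # --- coverage curves -------------------------------------------------
        stage = "coverage"
        curve_rows = []
        for expr_label in ("high", "medium_low", "zero"):
            promoters = RegionSet(
                f"promoters_{expr_label}",
                [
                    promoter_interval(
                        g, genome, config.promoter_upstream, config.promoter_downstream
                    )
                    for g in genes
                    if expr_classes[g.id].value == expr_label
                ],
            )
            if len(promoters) == 0:
                continue
            for include_singletons in (False, True):
                curve = coverage_curve(
                    promoters,
                    peaks_by_factor,
                    n_orders=config.n_coverage_orders,
                    seed=config.seed + 1,
                    include_singletons=include_singletons,
                    clusters=clusters,
                )
                for k, v in enumerate(curve.values):
                    curve_rows.append((expr_label, include_singletons, k, v))
        curve_table = pd.DataFrame(
            curve_rows, columns=["expression_class", "include_singletons", "k", "coverage"]
        )
        _write_tsv(curve_table, outdir / "coverage_curves.tsv")
        log["stages"][stage] = {"rows": len(curve_table)}

        # --- redundancy ratios ------------------------------------------------
        stage = "redundancy"
        red_rows = []
        for mark_name, track in marks.split.items():
            red_rows.append(
                (
                    mark_name,
                    redundancy_ratio(track, clusters),
                    redundancy_ratio(track, clusters + singletons),
                )
            )
        red_table = pd.DataFrame(
            red_rows, columns=["mark", "ratio_clusters", "ratio_with_singletons"]
        )
        _write_tsv(red_table, outdir / "redundancy_ratios.tsv")
        log["stages"][stage] = {"marks": len(red_rows)}

    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w") as handle:
        json.dump(log, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
    return log
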