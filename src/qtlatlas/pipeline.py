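"""End-to-end pipeline: anchor -> project -> regions -> candidates -> hubs.

The run report is a machine-readable view of the emitted TSVs (versions,
seeds, thresholds, per-stage counts, rejects with reasons); every number in
it is recomputable from the outputs.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from . import __version__
from .candidates import (
    assign_go_slim,
    degree_analysis,
    intersect_genes,
    select_hubs,
    stratify_candidates,
)
from .circos import export_circos
from .epcr import EpcrParams, anchor_markers
from .io import (
    load_chrom_sizes,
    load_genome_fasta,
    load_trait_catalog,
    read_edge_list,
    read_gene_annotation,
    read_go_mapping,
    read_qtl_table,
    write_atlas_tsv,
    write_candidates_tsv,
    write_hubs_tsv,
    write_marker_hits_tsv,
    write_regions,
)
from .model import QtlAtlasError, RunConfig
from .projection import ProjectionCalibration, build_atlas
from .regions import call_overlap_regions, detect_hot_regions, specificity_scan

log = logging.getLogger("qtlatlas")


@dataclass
class PipelineInputs:
    genome_fasta: str
    qtl_table: str
    chrom_sizes: Optional[str] = None
    trait_catalog: Optional[str] = None  # None -> bundled catalog
    genes: Optional[str] = None
    edges: Optional[str] = None
    go_slim: Optional[str] = None

    @classmethod
    def from_bundle(cls, bundle_dir) -> "PipelineInputs":
        """Wire up the file layout written by the synthetic-data generator."""
        d = Path(bundle_dir)
        opt = lambda name: str(d / name) if (d / name).exists() else None
        return cls(
            genome_fasta=str(d / "genome.fa"), qtl_table=str(d / "qtls.tsv"),
            chrom_sizes=opt("chrom_sizes.tsv"), trait_catalog=opt("trait_catalog.tsv"),
            genes=opt("genes.gff3"), edges=opt("edges.tsv"), go_slim=opt("go_slim.tsv"),
        )


def config_for_bundle(bundle_dir, **overrides) -> RunConfig:
    """A RunConfig whose cM->bp calibration matches a synthetic bundle's
    manifest."""
    with open(Path(bundle_dir) / "manifest.json") as fh:
        manifest = json.load(fh)
    cal = manifest.get("calibration", {})
    kwargs = {
        "cm_to_bp": cal.get("cm_to_bp", 425_000.0),
        "window_cM": cal.get("window_cM", 1.0),
    }
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def run_pipeline(inputs: PipelineInputs, config: Optional[RunConfig] = None,
                 outdir=None) -> dict:
    """Execute all stages; optional inputs (genes, edges) skip their stage
    with a notice. Returns the run report; with ``outdir`` all outputs and
    report.json are written."""
    config = config or RunConfig()
    report: dict = {
        "package": "qtlatlas", "version": __version__,
        "seed": config.rng_seed,
        "thresholds": {
            "min_categories": config.min_categories,
            "hot_threshold": config.hot_threshold,
            "hub_degree_threshold": config.hub_degree_threshold,
            "specificity_min_qtls": config.specificity_min_qtls,
            "max_mismatch": config.max_mismatch,
            "size_range": [config.size_min, config.size_max],
            "cm_to_bp": config.cm_to_bp, "window_cM": config.window_cM,
            "window_anchor": config.window_anchor,
            "region_merge_policy": config.region_merge_policy,
            "gene_intersection_mode": config.gene_intersection_mode,
        },
        "stages": {},
    }
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)
        return report["stages"].setdefault(name, {})

    try:
        s = stage("load")
        assembly = load_chrom_sizes(inputs.chrom_sizes) if inputs.chrom_sizes else None
        assembly = load_genome_fasta(inputs.genome_fasta, assembly)
        catalog = load_trait_catalog(inputs.trait_catalog)
        records, curation = read_qtl_table(inputs.qtl_table, catalog)
        s.update(n_chromosomes=len(assembly.chromosomes),
                 genome_bp=assembly.total_length,
                 qtl_rows_input=curation.n_input, qtl_rows_kept=curation.n_kept,
                 qtl_rows_dropped=curation.n_dropped, dropped=curation.dropped)

        s = stage("anchor")
        specs = [m for rec in records for m in rec.markers]
        params = EpcrParams(max_mismatch=config.max_mismatch,
                            size_range=(config.size_min, config.size_max))
        marker_map, anchor_report = anchor_markers(assembly, specs, params)
        s.update(n_markers=anchor_report.n_markers,
                 n_anchored=anchor_report.n_anchored,
                 unanchored=anchor_report.unanchored)

        s = stage("project")
        calibration = ProjectionCalibration(
            cm_to_bp=config.cm_to_bp, window_cM=config.window_cM,
            window_anchor=config.window_anchor,
        )
        atlas, summary = build_atlas(records, marker_map, calibration, catalog, assembly)
        s.update(summary.as_dict())

        s = stage("regions")
        regions, region_summary = call_overlap_regions(atlas, config)
        regions = detect_hot_regions(regions, config.hot_threshold)
        regions = specificity_scan(regions, atlas, "country", config.specificity_min_qtls)
        regions = specificity_scan(regions, atlas, "population", config.specificity_min_qtls)
        s.update(region_summary.as_dict())
        s.update(merge_policy=config.region_merge_policy,
                 n_hot=sum(r.hot for r in regions),
                 n_environment_specific=sum(r.environment_specific for r in regions),
                 n_population_specific=sum(r.population_specific for r in regions))

        candidates = None
        if inputs.genes:
            s = stage("candidates")
            genes = read_gene_annotation(inputs.genes, assembly)
            candidates = intersect_genes(genes, regions, config.gene_intersection_mode)
            strata = stratify_candidates(candidates)
            s.update(n_genes=len(genes), n_candidates=strata["total"],
                     by_multiplicity={str(k): v for k, v in sorted(strata["by_multiplicity"].items())},
                     by_chromosome=strata["by_chromosome"],
                     mode=config.gene_intersection_mode)
        else:
            report["stages"]["candidates"] = {"skipped": "no gene annotation provided"}

        nodes = None
        if inputs.edges:
            s = stage("network")
            network = read_edge_list(inputs.edges)
            nodes = degree_analysis(network)
            hubs = select_hubs(nodes, config.hub_degree_threshold)
            if inputs.go_slim:
                nodes = assign_go_slim(nodes, read_go_mapping(inputs.go_slim))
            s.update(n_nodes=network.n_nodes, n_edges=network.n_edges,
                     n_self_loops_dropped=network.n_self_loops_dropped,
                     n_hubs=len(hubs), hubs=sorted(h.gene_id for h in hubs))
        else:
            report["stages"]["network"] = {"skipped": "no edge list provided"}

        if outdir is not None:
            s = stage("export")
            write_marker_hits_tsv(marker_map, outdir / "markers_anchored.tsv")
            write_atlas_tsv(atlas.qtls, outdir / "atlas.tsv")
            write_regions(regions, outdir / "regions.tsv", "tsv")
            write_regions(regions, outdir / "regions.bed", "bed")
            if candidates is not None:
                write_candidates_tsv(candidates, outdir / "candidates.tsv")
            if nodes is not None:
                write_hubs_tsv(nodes, outdir / "network_nodes.tsv")
            export_circos(atlas, regions, outdir / "circos", config.min_categories)
            s.update(files=sorted(p.name for p in outdir.iterdir() if p.is_file()))
            with open(outdir / "report.json", "w") as fh:
                json.dump(report, fh, indent=1, sort_keys=True)
                fh.write("\n")
    except QtlAtlasError as exc:
        failed = list(report["stages"])[-1] if report["stages"] else "load"
        raise QtlAtlasError(f"pipeline aborted in stage {failed!r}: {exc}") from exc
    report["_objects"] = {  # in-memory handles for programmatic callers
        "atlas": atlas, "regions": regions, "candidates": candidates,
        "nodes": nodes, "marker_map": marker_map,
    }
    return report
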