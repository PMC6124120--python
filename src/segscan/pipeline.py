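"""Stage orchestration: run the requested stages in dependency order and
leave a deterministic artifact directory behind.

``simulate -> scan -> regions`` is the genome-scan arm; ``de``, ``strata``
and ``enrich`` run when their inputs are configured.  Every run writes a
``manifest.json`` recording parameters, seeds and package versions (no
timestamps, so fixed-seed runs are byte-identical)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, bsa_scan, de_filter, enrichment, io, phylostrata
from .config import load_config
from .synthetic_cross import CrossConfig, GenomeMap, Chromosome, default_genome, simulate_pool_counts

logger = logging.getLogger(__name__)

STAGE_ORDER = ["simulate", "scan", "regions", "de", "strata", "enrich"]


def genome_from_config(block: dict) -> GenomeMap:
    return default_genome(
        n_chromosomes=block["n_chromosomes"],
        markers_per_chromosome=block["markers_per_chromosome"],
        length_bp=block["chromosome_length_bp"],
        length_morgans=block["chromosome_length_morgans"],
    )


def cross_config_from(config: dict) -> CrossConfig:
    block = config["simulate"]
    return CrossConfig(
        genome=genome_from_config(block),
        causal_loci=tuple((str(c), int(p)) for c, p in block["causal_loci"]),
        phenotype_model=block["phenotype_model"],
        misclassification_rate=block["misclassification_rate"],
        pool_depth=tuple(block["pool_depth"]),
        seq_error_rate=block["seq_error_rate"],
        n_f2=block["n_f2"],
        n_f1=block["n_f1"],
        seed=config["seed"],
    )


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the artifact directory.

    ``config`` may be a loaded configuration dict (see
    :func:`segscan.config.load_config`) or a path to a YAML file.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config["log_level"]).upper(), logging.INFO))

    stages = list(config["stages"])
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]

    counts = None
    scan_df = None

    if "simulate" in stages:
        cross = cross_config_from(config)
        counts, truth = simulate_pool_counts(cross)
        io.write_pool_counts(counts, outdir / "counts.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)

    if "scan" in stages:
        if counts is None:
            src = config["scan"]["counts"]
            if src is None:
                candidate = outdir / "counts.tsv"
                if not candidate.exists():
                    raise FileNotFoundError(
                        "scan stage needs counts: run the simulate stage or set scan.counts"
                    )
                src = candidate
            counts = io.read_pool_counts(src)
        scan_df = bsa_scan.scan(
            counts, min_depth=config["scan"]["min_depth"], sided=config["scan"]["sided"]
        )
        io.write_scan(scan_df, outdir / "scan.tsv")

    if "regions" in stages:
        if scan_df is None:
            candidate = outdir / "scan.tsv"
            if not candidate.exists():
                raise FileNotFoundError("regions stage needs a scan: run the scan stage first")
            scan_df = io.read_scan(candidate)
        regions = bsa_scan.call_regions(
            scan_df, threshold=config["regions"]["threshold"],
            max_gap=config["regions"]["max_gap"],
        )
        io.write_regions(regions, outdir / "regions.bed")

    de_set = None
    if "de" in stages:
        block = config["de"]
        if block["fpkm"] is None:
            raise FileNotFoundError("de stage needs de.fpkm (an FPKM TSV path)")
        matrix = io.read_fpkm(block["fpkm"])
        qc = de_filter.replicate_correlation(matrix, qc_floor=block["qc_floor"])
        qc.to_csv(outdir / "replicate_qc.tsv", sep="\t", index=False, float_format="%.10g")
        mask = None
        if block["mask"]:
            mask = pd.read_csv(block["mask"], sep="\t", index_col=0).astype(bool)
        de_set = de_filter.select_de_genes(
            matrix, fold=block["fold"], pseudocount=block["pseudocount"], mask=mask
        )
        io.write_de_sets(de_set, outdir / "de_sets.tsv")
        io.write_gene_list(sorted(de_set.union), outdir / "de_genes.txt")

    assignments = None
    if "strata" in stages:
        block = config["strata"]
        for key in ("hits", "taxa", "universe"):
            if block[key] is None:
                raise FileNotFoundError(f"strata stage needs strata.{key}")
        ladder = phylostrata.load_taxon_map(block["taxa"])
        hits = phylostrata.filter_hits(io.read_hits(block["hits"]), e_max=block["e_max"])
        universe = io.read_gene_list(block["universe"])
        assignments = phylostrata.assign_phylostrata(hits, ladder, universe)
        assignments.to_csv(outdir / "strata.tsv", sep="\t")
        phylostrata.stratum_census(assignments, ladder).to_csv(
            outdir / "stratum_census.tsv", sep="\t"
        )

    if "enrich" in stages:
        block = config["enrich"]
        if block["annot"] is None and assignments is None:
            raise FileNotFoundError("enrich stage needs enrich.annot or a strata run")
        if block["annot"] is not None:
            annotations = io.read_annotations(block["annot"])
        else:
            annotations = phylostrata.strata_as_annotations(assignments)
        if block["universe"] is not None:
            universe = io.read_gene_list(block["universe"])
        elif assignments is not None:
            universe = list(assignments.index)
        else:
            universe = sorted(set().union(*annotations.values()))
        if block["set"] is not None:
            test_set = io.read_gene_list(block["set"])
        elif de_set is not None:
            test_set = sorted(de_set.union)
        else:
            raise FileNotFoundError("enrich stage needs enrich.set or a de run")
        results = enrichment.enrich(
            test_set, annotations, universe,
            alpha=block["alpha"], m=block["m"], method=block["method"],
        )
        io.write_enrichment(results, outdir / "enrichment.tsv")

    manifest = {
        "segscan_version": __version__,
        "config": _jsonable(config),
        "stages_run": stages,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
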