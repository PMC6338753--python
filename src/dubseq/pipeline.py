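"""End-to-end orchestration: files in, TSV artifacts out.

The pipeline runs the stages in assay order — barcode-pair association,
junction mapping, the reference-set join, per-sample counting, fragment and
gene scoring, effect calling and (optionally) the shuffle FDR — logging
per-stage read accounting so every input record is either used or counted
against a filter reason.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from pathlib import Path
from typing import Mapping, Sequence, Tuple

import pandas as pd
import yaml

from . import io as dio
from .barcodes import BarcodeCounts, FlankSpec, extract_barcode_with_tail, filter_one_off_barcodes
from .confidence import (
    Thresholds,
    call_high_confidence,
    call_reliable,
    estimate_fdr_by_shuffling,
)
from .counting import assemble_count_matrix, count_sample
from .library import (
    BarcodeMapping,
    GenomeIndex,
    ReferenceFragment,
    associate_barcode_pairs,
    build_reference_set,
    filter_chimeric_pairs,
    map_tail_to_genome,
    mapping_from_hit,
    resolve_barcode_locations,
)
from .reports import summarize_library, usable_read_percentage
from .scoring import (
    build_coverage_matrix,
    compute_fragment_scores,
    compute_gene_scores_nnls,
)

logger = logging.getLogger("dubseq")

__all__ = [
    "flank_spec_from_dict",
    "process_bagseq",
    "write_reference_fragments",
    "read_reference_fragments",
    "run_pipeline",
]


def flank_spec_from_dict(d: Mapping) -> FlankSpec:
    return FlankSpec(**d)


def write_reference_fragments(path, fragments: Sequence[ReferenceFragment]) -> None:
    frame = pd.DataFrame(
        {
            "up": [f.up for f in fragments],
            "down": [f.down for f in fragments],
            "contig": [f.contig for f in fragments],
            "start_1based": [f.start + 1 for f in fragments],
            "end_1based": [f.end for f in fragments],
            "length": [f.length for f in fragments],
        }
    )
    dio.write_tsv(path, frame, header_comment="coordinates are 1-based inclusive")


def read_reference_fragments(path) -> list[ReferenceFragment]:
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        ReferenceFragment(
            r.up, r.down, r.contig, int(r.start_1based) - 1, int(r.end_1based)
        )
        for r in frame.itertuples()
    ]


def process_bagseq(
    reads,
    spec: FlankSpec,
    index: GenomeIndex,
) -> Tuple[list[BarcodeMapping], dict]:
    """Junction mapping for one barcode tag.

    Extracts barcode + genomic tail from each read, maps each tail to its
    unique genomic location, applies the one-off filter to the barcode table
    and resolves each surviving barcode to its dominant junction.
    """
    per_barcode: Counter = Counter()
    tallies: dict[str, Counter] = defaultdict(Counter)
    total = extracted = mapped = 0
    for read_id, seq, quals in reads:
        total += 1
        hit_bc = extract_barcode_with_tail(seq, quals, spec, read_id=read_id)
        if hit_bc is None:
            continue
        extracted += 1
        hit = map_tail_to_genome(hit_bc.tail, index)
        if hit is None:
            continue
        mapped += 1
        mapping = mapping_from_hit(hit_bc.sequence, hit, len(hit_bc.tail))
        per_barcode[hit_bc.sequence] += 1
        tallies[hit_bc.sequence][
            (mapping.contig, mapping.junction, mapping.direction)
        ] += 1
    kept = set(
        filter_one_off_barcodes(
            BarcodeCounts(dict(per_barcode), mapped, mapped)
        ).counts
    )
    resolved = resolve_barcode_locations(
        {bc: dict(t) for bc, t in tallies.items() if bc in kept}
    )
    stats = {
        "total_reads": total,
        "barcode_extracted": extracted,
        "mapped": mapped,
        "barcodes_kept_one_off": len(kept),
        "barcodes_resolved": len(resolved),
    }
    return resolved, stats


def _write_mappings(path, mappings: Sequence[BarcodeMapping]) -> None:
    frame = pd.DataFrame(
        {
            "barcode": [m.barcode for m in mappings],
            "contig": [m.contig for m in mappings],
            "junction_1based": [m.junction + 1 for m in mappings],
            "direction": [m.direction for m in mappings],
            "count": [m.read_count for m in mappings],
        }
    )
    dio.write_tsv(path, frame, header_comment="junctions are 1-based")


def run_pipeline(config: Mapping, outdir=None) -> dict:
    """Run every stage described by ``config``; returns in-memory artifacts.

    ``config`` is the dict form of the YAML pipeline configuration (paths to
    genome, genes, design, per-assay FASTQ files and flank specs).  When
    ``outdir`` (or ``config['outdir']``) is set, all artifacts are also
    written as TSV.
    """
    outdir = Path(outdir or config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("genome_fasta", "genes", "design"):
        if key not in config:
            raise dio.ConfigurationError(f"pipeline config is missing {key!r}")
        if not Path(config[key]).exists():
            raise dio.ConfigurationError(f"{key} file not found: {config[key]}")

    genome = dio.read_fasta(config["genome_fasta"])
    genes = dio.read_genes(config["genes"])
    design = dio.read_design(config["design"])
    specs = {k: flank_spec_from_dict(v) for k, v in config["flank_specs"].items()}
    thresholds = Thresholds(**config.get("thresholds", {}))
    stats: dict[str, dict] = {}

    # --- barcode pairs -----------------------------------------------------
    logger.info("stage bpseq: associating barcode pairs")
    assoc = associate_barcode_pairs(
        dio.read_fastq(config["bpseq_fastq"]), specs["bpseq_up"], specs["bpseq_down"]
    )
    pairs = filter_chimeric_pairs(assoc.pairs)
    stats["bpseq"] = {
        "total_reads": assoc.total_reads,
        "usable_reads": assoc.usable_reads,
        "pairs_after_one_off": len(assoc.pairs),
        "pairs_after_chimera_filter": len(pairs),
        "usable_read_pct": usable_read_percentage(
            assoc.total_reads, assoc.usable_reads
        ),
    }
    dio.write_tsv(
        outdir / "bpseq_pairs.tsv",
        pd.DataFrame(
            {"up": [p.up for p in pairs], "down": [p.down for p in pairs],
             "count": [p.read_count for p in pairs]}
        ),
    )

    # --- junction mapping --------------------------------------------------
    index = GenomeIndex(genome)
    logger.info("stage bagseq: mapping barcode junctions")
    up_maps, up_stats = process_bagseq(
        dio.read_fastq(config["bagseq_up_fastq"]), specs["bagseq_up"], index
    )
    down_maps, down_stats = process_bagseq(
        dio.read_fastq(config["bagseq_down_fastq"]), specs["bagseq_down"], index
    )
    stats["bagseq_up"], stats["bagseq_down"] = up_stats, down_stats
    _write_mappings(outdir / "bagseq_up.tsv", up_maps)
    _write_mappings(outdir / "bagseq_down.tsv", down_maps)

    # --- the join ----------------------------------------------------------
    logger.info("stage bpag: joining pairs with junctions")
    fragments, dropped = build_reference_set(pairs, up_maps, down_maps)
    stats["bpag"] = {"fragments": len(fragments), **{f"dropped_{k}": v for k, v in dropped.items()}}
    write_reference_fragments(outdir / "reference_fragments.tsv", fragments)

    # --- counting ----------------------------------------------------------
    logger.info("stage barseq: counting samples")
    sample_counts = {}
    for sample_id, path in config["barseq_fastq"].items():
        sample_counts[sample_id] = count_sample(dio.read_fastq(path), specs["barseq"])
    matrix = assemble_count_matrix(sample_counts, fragments, design)
    stats["barseq"] = {
        s: {"total": int(matrix.totals[s]), "usable": int(matrix.usable[s]),
            "unmapped": int(matrix.unmapped[s])}
        for s in matrix.samples
    }
    counts_out = matrix.counts.copy()
    counts_out.index.name = "barcode"
    dio.write_tsv(outdir / "counts.tsv", counts_out.reset_index())

    # --- scoring -----------------------------------------------------------
    logger.info("stage fscore/gscore: fitness scores")
    coverage = build_coverage_matrix(
        fragments, genes, {c: len(s) for c, s in genome.items()}
    )
    condition_samples = design.loc[~design["is_time_zero"], "sample_id"].tolist()
    scores_by_exp = {}
    gene_scores_by_exp = {}
    calls = []
    for sample in condition_samples:
        scores = compute_fragment_scores(matrix, design, sample)
        scores_by_exp[sample] = scores
        out = scores.reset_index()
        dio.write_tsv(outdir / f"fragment_scores.{sample}.tsv", out)
        gene_scores = compute_gene_scores_nnls(scores, coverage)
        gene_scores_by_exp[sample] = gene_scores
        exportable = gene_scores.drop(columns="fragment_ids").reset_index()
        dio.write_tsv(outdir / f"gene_scores.{sample}.tsv", exportable)
        calls.append(call_reliable(gene_scores, scores, sample, thresholds))

    # --- effect calling ----------------------------------------------------
    logger.info("stage confidence: effect calling")
    compound_map = dict(zip(design["sample_id"], design["condition"]))
    all_calls = call_high_confidence(
        pd.concat(calls, ignore_index=True), compound_map, thresholds
    )
    dio.write_tsv(outdir / "effect_calls.tsv", all_calls)
    stats["confidence"] = {
        "reliable": int(all_calls["reliable"].sum()),
        "high_confidence": int(all_calls["high_confidence"].sum()),
    }

    # --- optional shuffle FDR ---------------------------------------------
    fdr = None
    if config.get("fdr"):
        fdr_cfg = config["fdr"]
        fdr = estimate_fdr_by_shuffling(
            scores_by_exp,
            coverage,
            compound_map,
            n_shuffles=int(fdr_cfg.get("n_shuffles", 10)),
            seed=int(fdr_cfg.get("seed", 0)),
            thresholds=thresholds,
        )
        dio.write_tsv(
            outdir / "fdr.tsv",
            pd.DataFrame(
                {
                    "shuffle": range(1, fdr.n_shuffles + 1),
                    "high_confidence_effects": fdr.shuffled_counts,
                    "actual_count": fdr.actual_count,
                    "fdr": "NA" if fdr.fdr is None else fdr.fdr,
                }
            ),
        )
        stats["fdr"] = {
            "actual": fdr.actual_count,
            "mean_shuffled": float(pd.Series(fdr.shuffled_counts).mean()),
            "fdr": fdr.fdr,
        }

    # --- library summary ---------------------------------------------------
    summary = summarize_library(
        fragments, genes, {c: len(s) for c, s in genome.items()}
    )
    dio.write_tsv(outdir / "library_cumulative_coverage.tsv", summary.cumulative_coverage)
    dio.write_tsv(outdir / "library_window_coverage.tsv", summary.window_coverage)

    with open(outdir / "stage_stats.yaml", "w") as handle:
        yaml.safe_dump(stats, handle, sort_keys=True)

    return {
        "pairs": pairs,
        "fragments": fragments,
        "matrix": matrix,
        "scores_by_experiment": scores_by_exp,
        "gene_scores_by_experiment": gene_scores_by_exp,
        "effect_calls": all_calls,
        "fdr": fdr,
        "summary": summary,
        "stats": stats,
    }


def load_config(path) -> dict:
    with open(path) as handle:
        config = yaml.safe_load(handle)
    base = Path(path).parent
    # resolve relative paths against the config file location
    def _resolve(value):
        p = base / value
        return str(p) if p.exists() else value

    for key in ("genome_fasta", "genes", "design", "bpseq_fastq",
                "bagseq_up_fastq", "bagseq_down_fastq"):
        if key in config:
            config[key] = _resolve(config[key])
    if "barseq_fastq" in config:
        config["barseq_fastq"] = {
            k: _resolve(v) for k, v in config["barseq_fastq"].items()
        }
    return config
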