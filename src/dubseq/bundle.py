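"""Write a complete simulated input bundle that the pipeline can consume.

Produces genome FASTA, gene and design tables, FASTQ for every assay, truth
tables, and a ready-to-run ``config.yaml`` whose flank specs match the
simulated read layout.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .simulate import (
    SimConfig,
    TruthTables,
    bagseq_flank_spec,
    barseq_flank_spec,
    bpseq_flank_specs,
    make_design,
    simulate_barseq_reads,
    simulate_fitness_counts,
    simulate_genome_and_genes,
    simulate_library,
    simulate_reads,
)

__all__ = ["write_bundle"]


def _spec_dict(spec) -> dict:
    return {
        "upstream_anchor": spec.upstream_anchor,
        "downstream_anchor": spec.downstream_anchor,
        "expected_start": spec.expected_start,
        "barcode_length": spec.barcode_length,
    }


def write_bundle(config: SimConfig, outdir, design: pd.DataFrame | None = None) -> TruthTables:
    """Simulate a full study under ``config`` and write it to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome_and_genes(config)
    truth = simulate_library(config, genome, genes)
    if design is None:
        design = make_design()

    dio.write_fasta(outdir / "genome.fasta", genome)
    dio.write_genes(outdir / "genes.tsv", genes)
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    truth.fragments.to_csv(outdir / "truth_fragments.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": list(truth.effects), "beta": list(truth.effects.values())}
    ).to_csv(outdir / "truth_effects.tsv", sep="\t", index=False)

    dio.write_fastq(outdir / "bpseq.fastq", simulate_reads(truth, "bpseq"))
    dio.write_fastq(outdir / "bagseq_up.fastq", simulate_reads(truth, "bagseq_up"))
    dio.write_fastq(outdir / "bagseq_down.fastq", simulate_reads(truth, "bagseq_down"))

    matrix = simulate_fitness_counts(truth, design)
    barseq_paths = {}
    for sample in matrix.samples:
        path = outdir / f"barseq.{sample}.fastq"
        dio.write_fastq(path, simulate_barseq_reads(truth, matrix.counts[sample]))
        barseq_paths[sample] = path.name
    matrix.counts.rename_axis("barcode").reset_index().to_csv(
        outdir / "truth_counts.tsv", sep="\t", index=False
    )

    up_spec, down_spec = bpseq_flank_specs(config.barcode_length)
    pipeline_config = {
        "genome_fasta": "genome.fasta",
        "genes": "genes.tsv",
        "design": "design.tsv",
        "bpseq_fastq": "bpseq.fastq",
        "bagseq_up_fastq": "bagseq_up.fastq",
        "bagseq_down_fastq": "bagseq_down.fastq",
        "barseq_fastq": barseq_paths,
        "flank_specs": {
            "bpseq_up": _spec_dict(up_spec),
            "bpseq_down": _spec_dict(down_spec),
            "bagseq_up": _spec_dict(bagseq_flank_spec("up", config.barcode_length)),
            "bagseq_down": _spec_dict(bagseq_flank_spec("down", config.barcode_length)),
            "barseq": _spec_dict(barseq_flank_spec("up", config.barcode_length)),
        },
        "fdr": {"n_shuffles": 10, "seed": config.seed},
    }
    with open(outdir / "config.yaml", "w") as handle:
        yaml.safe_dump(pipeline_config, handle, sort_keys=False)
    with open(outdir / "sim_config.yaml", "w") as handle:
        yaml.safe_dump(asdict(config), handle, sort_keys=False)
    return truth
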