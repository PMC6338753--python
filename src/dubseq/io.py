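"""File-format helpers: FASTQ/FASTA (gzip-transparent), design/gene/operon
tables and the pipeline's TSV artifacts.

Coordinate convention: everything in memory is 0-based, half-open.  Exported
TSVs use 1-based inclusive coordinates (``start_1based``/``end_1based``
columns); readers convert back.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

PathLike = Union[str, Path]

DESIGN_COLUMNS = ["sample_id", "set_id", "condition", "is_time_zero", "replicate_group"]


class ConfigurationError(RuntimeError):
    """Bad or inconsistent pipeline configuration (missing files/samples)."""


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: PathLike) -> Iterator[Tuple[str, str, list[int]]]:
    """Yield ``(read_id, sequence, qualities)`` from a (possibly gzipped) FASTQ."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(path: PathLike, reads: Iterable[Tuple[str, str, Sequence[int]]]) -> int:
    """Write ``(read_id, sequence, qualities)`` records; returns record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read_id, seq, quals in reads:
            qual_str = "".join(chr(q + 33) for q in quals)
            handle.write(f"@{read_id}\n{seq}\n+\n{qual_str}\n")
            n += 1
    return n


def read_fasta(path: PathLike) -> dict[str, str]:
    """Load a FASTA file into ``{contig: sequence}``."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path: PathLike, contigs: dict[str, str], width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in contigs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_design(path: PathLike) -> pd.DataFrame:
    """Read the experiment design table and validate its invariants.

    Columns: sample_id, set_id, condition, is_time_zero, replicate_group.
    Every set must contain at least one time-zero sample and sample ids must
    be unique.
    """
    design = pd.read_csv(path, sep="\t", comment="#")
    return validate_design(design)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ConfigurationError(f"design table is missing columns: {missing}")
    design = design.copy()
    design["is_time_zero"] = design["is_time_zero"].astype(bool)
    if design["sample_id"].duplicated().any():
        dupes = design.loc[design["sample_id"].duplicated(), "sample_id"].tolist()
        raise ConfigurationError(f"duplicate sample_ids in design: {dupes}")
    for set_id, grp in design.groupby("set_id"):
        if not grp["is_time_zero"].any():
            raise ConfigurationError(f"set {set_id!r} has no time-zero sample")
    return design


def read_genes(path: PathLike) -> pd.DataFrame:
    """Read a gene annotation as TSV or GFF3 into 0-based half-open intervals.

    TSV columns: gene_id, contig, start_1based, end_1based, strand.
    GFF3: rows of type ``gene`` (or ``CDS`` when no genes present) with an
    ``ID=`` or ``locus_tag=`` attribute.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_genes_gff3(path)
    genes = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "contig", "start_1based", "end_1based"}
    if not required.issubset(genes.columns):
        raise ConfigurationError(f"gene table must have columns {sorted(required)}")
    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"].astype(str),
            "contig": genes["contig"].astype(str),
            "start": genes["start_1based"].astype(int) - 1,
            "end": genes["end_1based"].astype(int),
            "strand": genes.get("strand", pd.Series(["+"] * len(genes))),
        }
    )
    return out


def _read_genes_gff3(path: PathLike) -> pd.DataFrame:
    rows = []
    with _open_text(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in {"gene", "CDS"}:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name")
            rows.append(
                {
                    "gene_id": gene_id,
                    "contig": parts[0],
                    "start": int(parts[3]) - 1,
                    "end": int(parts[4]),
                    "strand": parts[6],
                    "type": parts[2],
                }
            )
    genes = pd.DataFrame(rows)
    if genes.empty:
        raise ConfigurationError(f"no gene/CDS features found in {path}")
    if (genes["type"] == "gene").any():
        genes = genes[genes["type"] == "gene"]
    return genes.drop(columns="type").reset_index(drop=True)


def write_genes(path: PathLike, genes: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "contig": genes["contig"],
            "start_1based": genes["start"] + 1,
            "end_1based": genes["end"],
            "strand": genes.get("strand", "+"),
        }
    )
    with open(path, "w") as handle:
        handle.write("# coordinates are 1-based inclusive\n")
        out.to_csv(handle, sep="\t", index=False)


def read_operons(path: PathLike) -> pd.DataFrame:
    """Read a user-supplied operon-position table.

    Columns: gene_id, position ('first' or 'later'); an optional ``evidence``
    column is honoured by dropping rows whose evidence is 'weak'.  Genes
    listed both as first and later (in different transcripts) are excluded.
    """
    tab = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "position"}.issubset(tab.columns):
        raise ConfigurationError("operon table needs columns gene_id, position")
    if "evidence" in tab.columns:
        tab = tab[tab["evidence"].str.lower() != "weak"]
    bad = tab[~tab["position"].isin(["first", "later"])]
    if not bad.empty:
        raise ConfigurationError(
            f"operon positions must be 'first' or 'later', got {bad['position'].unique()}"
        )
    n_positions = tab.groupby("gene_id")["position"].nunique()
    ambiguous = set(n_positions[n_positions > 1].index)
    tab = tab[~tab["gene_id"].isin(ambiguous)].drop_duplicates("gene_id")
    return tab.reset_index(drop=True)


def write_tsv(path: PathLike, frame: pd.DataFrame, header_comment: str | None = None) -> None:
    with open(path, "w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        frame.to_csv(handle, sep="\t", index=False)
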