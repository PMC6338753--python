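"""Library-characterization summaries and bookkeeping statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .library import ReferenceFragment
from .scoring import build_coverage_matrix

__all__ = ["LibrarySummary", "summarize_library", "usable_read_percentage"]

WINDOW_SIZE = 10_000


@dataclass
class LibrarySummary:
    """Descriptive statistics of a barcoded-fragment library.

    ``fragment_lengths``: every fragment's length (nt).
    ``genes_per_fragment``: count of fragments by number of genes fully covered.
    ``fragments_per_gene``: per-gene count of fully covering fragments
    (genes covered by none appear with 0).
    ``cumulative_coverage``: for each k, percentage of genes covered by >= k
    independent fragments.
    ``window_coverage``: number of fragments overlapping each fixed genomic
    window.
    """

    fragment_lengths: pd.Series
    genes_per_fragment: pd.Series
    fragments_per_gene: pd.Series
    cumulative_coverage: pd.DataFrame
    window_coverage: pd.DataFrame


def summarize_library(
    fragments: Sequence[ReferenceFragment],
    genes: pd.DataFrame,
    contig_lengths: Optional[Mapping[str, int]] = None,
    window_size: int = WINDOW_SIZE,
) -> LibrarySummary:
    """Compute all library summaries from the reference set and annotation."""
    lengths = pd.Series([f.length for f in fragments], name="length")
    coverage = build_coverage_matrix(fragments, genes)
    per_fragment = coverage.matrix.sum(axis=1)
    genes_per_fragment = (
        pd.Series(per_fragment).value_counts().sort_index().rename("n_fragments")
    )
    per_gene = pd.Series(
        coverage.matrix.sum(axis=0), index=coverage.gene_ids, name="n_fragments"
    )
    max_k = int(per_gene.max()) if len(per_gene) else 0
    ks = np.arange(0, max_k + 1)
    pct = [100.0 * float((per_gene >= k).mean()) for k in ks]
    cumulative = pd.DataFrame({"k": ks, "pct_genes_covered_ge_k": pct})

    if contig_lengths is None:
        contig_lengths = {}
        for f in fragments:
            contig_lengths[f.contig] = max(contig_lengths.get(f.contig, 0), f.end)
    rows = []
    for contig, clen in sorted(contig_lengths.items()):
        for w_start in range(0, clen, window_size):
            w_end = min(w_start + window_size, clen)
            n = sum(
                1
                for f in fragments
                if f.contig == contig and f.start < w_end and f.end > w_start
            )
            rows.append(
                {"contig": contig, "window_start": w_start, "window_end": w_end,
                 "n_fragments": n}
            )
    window_coverage = pd.DataFrame(rows)
    return LibrarySummary(
        fragment_lengths=lengths,
        genes_per_fragment=genes_per_fragment,
        fragments_per_gene=per_gene,
        cumulative_coverage=cumulative,
        window_coverage=window_coverage,
    )


def usable_read_percentage(total_reads: int, usable_reads: int) -> Optional[float]:
    """Percentage of reads supporting the reference set; ``None`` when no reads."""
    if usable_reads > total_reads:
        raise ValueError("usable_reads cannot exceed total_reads")
    if total_reads == 0:
        return None
    return 100.0 * usable_reads / total_reads
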