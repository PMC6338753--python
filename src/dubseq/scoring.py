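"""Fragment fitness scores and NNLS gene-score deconvolution.

A fragment's fitness in one experiment is

    f_i = log2((s_i + 1) / (t_i + 1)) - median over valid fragments,

where ``s_i`` is the fragment's barcode count in the condition sample and
``t_i`` the sum of its counts across the experiment set's time-zero samples.
Only barcodes with at least 10 reads in some time-zero sample are scored.

Gene scores model each fragment's fitness as the sum of the fitness effects
of the genes it covers start-to-stop: f = A g with A binary.  Ordinary least
squares overfits badly on this design, so the effects are estimated with
non-negative least squares — one pass for benefits (g >= 0 against f) and a
second pass against -f for detrimental effects; the reported signed score is
``score_pos - score_neg``.  A simple covering-fragment mean score is also
computed; it is biased upward for neutral genes that ride along on fragments
carrying a causative neighbour, which is exactly what the regression
removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .counting import CountMatrix
from .io import ConfigurationError, validate_design
from .library import ReferenceFragment

__all__ = [
    "CoverageMatrix",
    "GeneScoreResult",
    "CloneEstimate",
    "select_valid_barcodes",
    "compute_fragment_scores",
    "build_coverage_matrix",
    "compute_gene_scores_mean",
    "compute_gene_scores_nnls",
    "compute_gene_pair_scores",
    "estimate_clone_requirement",
]

MIN_T0_READS = 10


@dataclass
class CoverageMatrix:
    """Binary fragments x genes complete-coverage matrix.

    ``matrix[i, j] == 1`` iff fragment i contains gene j from start to stop
    (strand-agnostic interval containment).
    """

    matrix: np.ndarray
    fragment_barcodes: list[str]
    gene_ids: list[str]

    def restrict_fragments(self, barcodes: Sequence[str]) -> "CoverageMatrix":
        index = {b: i for i, b in enumerate(self.fragment_barcodes)}
        rows = [index[b] for b in barcodes]
        return CoverageMatrix(self.matrix[rows], list(barcodes), list(self.gene_ids))


@dataclass(frozen=True)
class GeneScoreResult:
    gene_id: str
    score: float
    score_pos: float
    score_neg: float
    score_mean: float
    n_fragments: int
    fragment_ids: tuple[str, ...]


@dataclass(frozen=True)
class CloneEstimate:
    """Clones needed to cover a genome with random inserts.

    N = ln(1 - coverage_prob) / ln(1 - insert_size / genome_size), rounded up.
    """

    n_clones: int
    insert_size: int
    genome_size: int
    coverage_prob: float


# ---------------------------------------------------------------------------
# Fragment scores
# ---------------------------------------------------------------------------

def _set_of_sample(design: pd.DataFrame, sample: str) -> str:
    row = design.loc[design["sample_id"] == sample]
    if row.empty:
        raise ConfigurationError(f"sample {sample!r} not in design")
    return row["set_id"].iloc[0]


def _time_zero_samples(design: pd.DataFrame, set_id: str) -> list[str]:
    t0 = design.loc[
        (design["set_id"] == set_id) & design["is_time_zero"], "sample_id"
    ].tolist()
    if not t0:
        raise ConfigurationError(f"set {set_id!r} has no time-zero sample")
    return t0


def select_valid_barcodes(
    matrix: CountMatrix,
    design: pd.DataFrame,
    set_id: str,
    min_t0_reads: int = MIN_T0_READS,
) -> set[str]:
    """Barcodes with >= ``min_t0_reads`` reads in at least one time-zero
    sample of the set — the only ones whose fitness can be trusted."""
    design = validate_design(design)
    t0 = _time_zero_samples(design, set_id)
    sub = matrix.counts[t0]
    return set(sub.index[(sub >= min_t0_reads).any(axis=1)])


def compute_fragment_scores(
    matrix: CountMatrix,
    design: pd.DataFrame,
    condition_sample: str,
    min_t0_reads: int = MIN_T0_READS,
) -> pd.DataFrame:
    """Fragment fitness scores for one condition sample.

    Returns a frame indexed by barcode with columns ``s`` (condition count),
    ``t`` (summed time-zero count), ``f_raw`` and the median-centered ``f``.
    Only valid barcodes appear.
    """
    design = validate_design(design)
    set_id = _set_of_sample(design, condition_sample)
    t0 = _time_zero_samples(design, set_id)
    valid = select_valid_barcodes(matrix, design, set_id, min_t0_reads)
    barcodes = [b for b in matrix.counts.index if b in valid]
    s = matrix.counts.loc[barcodes, condition_sample].to_numpy(dtype=float)
    t = matrix.counts.loc[barcodes, t0].sum(axis=1).to_numpy(dtype=float)
    f_raw = np.log2((s + 1.0) / (t + 1.0))
    f = f_raw - np.median(f_raw) if len(f_raw) else f_raw
    return pd.DataFrame(
        {"s": s.astype(int), "t": t.astype(int), "f_raw": f_raw, "f": f},
        index=pd.Index(barcodes, name="barcode"),
    )


# ---------------------------------------------------------------------------
# Gene coverage and gene scores
# ---------------------------------------------------------------------------

def build_coverage_matrix(
    fragments: Sequence[ReferenceFragment],
    genes: pd.DataFrame,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> CoverageMatrix:
    """Binary complete-coverage matrix of fragments over genes.

    ``genes`` needs columns gene_id, contig, start, end (0-based half-open).
    Containment is inclusive: a gene exactly equal to the fragment interval
    counts as covered.
    """
    if contig_lengths is not None:
        for _, g in genes.iterrows():
            limit = contig_lengths.get(g["contig"])
            if limit is not None and (g["start"] < 0 or g["end"] > limit):
                raise ValueError(
                    f"gene {g['gene_id']} [{g['start']},{g['end']}) exceeds "
                    f"contig {g['contig']} bounds"
                )
    n_frag, n_gene = len(fragments), len(genes)
    A = np.zeros((n_frag, n_gene), dtype=np.int8)
    gene_ids = genes["gene_id"].astype(str).tolist()
    g_contig = genes["contig"].to_numpy()
    g_start = genes["start"].to_numpy(dtype=int)
    g_end = genes["end"].to_numpy(dtype=int)
    for i, frag in enumerate(fragments):
        A[i] = (
            (g_contig == frag.contig) & (g_start >= frag.start) & (g_end <= frag.end)
        )
    return CoverageMatrix(A, [f.up for f in fragments], gene_ids)


def compute_gene_scores_mean(
    scores: pd.DataFrame, coverage: CoverageMatrix
) -> pd.Series:
    """Per-gene mean of the covering valid fragments' fitness scores.

    Genes covered by no valid fragment are absent from the result.
    """
    present = [b for b in coverage.fragment_barcodes if b in scores.index]
    cov = coverage.restrict_fragments(present)
    f = scores.loc[present, "f"].to_numpy(dtype=float)
    A = cov.matrix.astype(float)
    n_cover = A.sum(axis=0)
    means = {}
    for j, gene in enumerate(cov.gene_ids):
        if n_cover[j] > 0:
            means[gene] = float(A[:, j] @ f / n_cover[j])
    return pd.Series(means, name="score_mean")


def _nnls_signed(A: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two NNLS passes: benefits against f, detriments against -f."""
    pos, _ = nnls(A, f)
    neg, _ = nnls(A, -f)
    return pos, neg


def compute_gene_scores_nnls(
    scores: pd.DataFrame, coverage: CoverageMatrix
) -> pd.DataFrame:
    """Deconvolve fragment fitness into per-gene scores with NNLS.

    Rows of the coverage matrix are restricted to valid, scored fragments;
    genes with an all-zero column (no covering valid fragment) are excluded
    from the regression and reported as missing, not zero.  Returns a frame
    indexed by gene_id with columns score, score_pos, score_neg, score_mean,
    n_fragments, fragment_ids.
    """
    present = [b for b in coverage.fragment_barcodes if b in scores.index]
    if not present:
        return pd.DataFrame(
            columns=["score", "score_pos", "score_neg", "score_mean", "n_fragments", "fragment_ids"]
        )
    cov = coverage.restrict_fragments(present)
    f = scores.loc[present, "f"].to_numpy(dtype=float)
    A = cov.matrix.astype(float)
    covered = A.sum(axis=0) > 0
    if not covered.any():
        return pd.DataFrame(
            columns=["score", "score_pos", "score_neg", "score_mean", "n_fragments", "fragment_ids"]
        )
    A_red = A[:, covered]
    gene_ids = [g for g, c in zip(cov.gene_ids, covered) if c]
    pos, neg = _nnls_signed(A_red, f)
    n_fragments = A_red.sum(axis=0).astype(int)
    mean = (A_red.T @ f) / n_fragments
    frag_array = np.asarray(present, dtype=object)
    records = []
    for j, gene in enumerate(gene_ids):
        covering = tuple(frag_array[A_red[:, j] > 0])
        records.append(
            {
                "gene_id": gene,
                "score": float(pos[j] - neg[j]),
                "score_pos": float(pos[j]),
                "score_neg": float(neg[j]),
                "score_mean": float(mean[j]),
                "n_fragments": int(n_fragments[j]),
                "fragment_ids": covering,
            }
        )
    return pd.DataFrame(records).set_index("gene_id")


# ---------------------------------------------------------------------------
# Adjacent-gene (epistasis) pairs
# ---------------------------------------------------------------------------

def _adjacent_pairs(genes: pd.DataFrame) -> list[tuple[str, str]]:
    ordered = genes.sort_values(["contig", "start"])
    pairs = []
    prev = None
    for _, row in ordered.iterrows():
        if prev is not None and prev["contig"] == row["contig"]:
            pairs.append((str(prev["gene_id"]), str(row["gene_id"])))
        prev = row
    return pairs


def compute_gene_pair_scores(
    scores_by_experiment: Mapping[str, pd.DataFrame],
    coverage: CoverageMatrix,
    genes: pd.DataFrame,
    min_supporting_fragments: int = 2,
) -> pd.DataFrame:
    """Score adjacent gene pairs for synergy beyond their single-gene effects.

    For each experiment (the replicates of one condition) the design matrix
    gains one column per adjacent gene pair, set for fragments covering both
    genes entirely (and hence the intergenic region between them); the NNLS
    passes are re-run.  A pair passes iff, in *every* experiment, its score
    exceeds both single-gene scores and it is supported by at least
    ``min_supporting_fragments`` fragments.  Reported ``pair_score`` is the
    mean over experiments.
    """
    pairs = _adjacent_pairs(genes)
    gene_pos = {g: j for j, g in enumerate(coverage.gene_ids)}
    # per-experiment pieces shared by all pairs
    prepared = {}
    for exp, scores in scores_by_experiment.items():
        present = [b for b in coverage.fragment_barcodes if b in scores.index]
        cov = coverage.restrict_fragments(present)
        f = scores.loc[present, "f"].to_numpy(dtype=float)
        A = cov.matrix.astype(float)
        single = compute_gene_scores_nnls(scores, coverage)
        prepared[exp] = (A, f, single)
    records = []
    for gene_a, gene_b in pairs:
        ja, jb = gene_pos[gene_a], gene_pos[gene_b]
        per_exp_scores = []
        per_exp_pass = []
        supporting = None
        for exp, (A, f, single) in prepared.items():
            pair_col = (A[:, ja] * A[:, jb]).reshape(-1, 1)
            n_support = int(pair_col.sum())
            if supporting is None or n_support < supporting:
                supporting = n_support
            if n_support == 0:
                per_exp_pass.append(False)
                per_exp_scores.append(0.0)
                continue
            covered = A.sum(axis=0) > 0
            aug = np.hstack([A[:, covered], pair_col])
            pos, neg = _nnls_signed(aug, f)
            pair_score = float(pos[-1] - neg[-1])
            score_a = float(single["score"].get(gene_a, 0.0))
            score_b = float(single["score"].get(gene_b, 0.0))
            ok = (
                pair_score > score_a
                and pair_score > score_b
                and n_support >= min_supporting_fragments
            )
            per_exp_pass.append(ok)
            per_exp_scores.append(pair_score)
        records.append(
            {
                "gene_a": gene_a,
                "gene_b": gene_b,
                "pair_score": float(np.mean(per_exp_scores)) if per_exp_scores else 0.0,
                "supporting_fragments": int(supporting or 0),
                "passes": bool(per_exp_pass) and all(per_exp_pass),
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Library design helper
# ---------------------------------------------------------------------------

def estimate_clone_requirement(
    insert_size: int, genome_size: int, coverage_prob: float = 0.99
) -> CloneEstimate:
    """Clones required so each genomic locus is present with the given
    probability (Clarke-Carbon formula), rounded up."""
    if not 0 < insert_size < genome_size:
        raise ValueError("require 0 < insert_size < genome_size")
    if not 0 < coverage_prob < 1:
        raise ValueError("require 0 < coverage_prob < 1")
    n = math.log(1.0 - coverage_prob) / math.log(1.0 - insert_size / genome_size)
    return CloneEstimate(
        n_clones=math.ceil(n),
        insert_size=insert_size,
        genome_size=genome_size,
        coverage_prob=coverage_prob,
    )
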