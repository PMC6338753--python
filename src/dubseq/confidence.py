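"""Effect calling, replicate consistency, shuffle-FDR and operon comparison.

A gene x experiment effect is *reliable* when three filters pass:

1. magnitude — |regression gene score| >= 2;
2. consistency — the covering fragments' scores agree (one-sample t-test,
   p < 0.05, against a reference that absorbs centering uncertainty; a gene
   with a single fragment instead needs |f| in the experiment's top 1%);
3. noise — |z| >= 4, where z = mean(fragment f) / gene noise and the gene
   noise propagates the Poisson counting noise of each covering fragment,
   sqrt(1/(1+s) + 1/(1+t)) / ln 2.

A reliable effect is *high confidence* when it rests on more than one
fragment, or when another experiment with the same compound shows a large
(|score| >= 2) effect for the gene.  The false discovery rate is estimated
by shuffling the barcode-to-fragment assignment and re-calling effects from
mean gene scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import CoverageMatrix, compute_gene_scores_nnls

__all__ = [
    "Thresholds",
    "NoiseEstimate",
    "FdrEstimate",
    "OperonComparison",
    "gene_noise_z",
    "consistency_test",
    "call_reliable",
    "call_high_confidence",
    "replicate_consistency",
    "expected_false_positives",
    "estimate_fdr_by_shuffling",
    "operon_position_comparison",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Thresholds:
    """The effect-calling filter thresholds."""

    min_abs_score: float = 2.0
    max_p: float = 0.05
    min_abs_z: float = 4.0
    top_fraction: float = 0.01  # single-fragment rule
    replicate_min_abs_score: float = 1.5


@dataclass(frozen=True)
class NoiseEstimate:
    """Poisson-propagated noise of a gene's fragment-score mean."""

    fragment_noise: Tuple[float, ...]
    gene_noise: float
    z: float


@dataclass
class FdrEstimate:
    """Shuffle-based false discovery rate for high-confidence effects.

    ``fdr`` is mean(shuffled counts) / actual count, or ``None`` (not
    applicable) when no genuine effects were called.
    """

    n_shuffles: int
    shuffled_counts: list[int]
    actual_count: int
    seed: int
    fdr: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if self.fdr is None and self.actual_count > 0:
            self.fdr = float(np.mean(self.shuffled_counts)) / self.actual_count


@dataclass(frozen=True)
class OperonComparison:
    """First-in-transcript vs later genes, by high-confidence effect status."""

    table: Tuple[Tuple[int, int], Tuple[int, int]]
    prop_first: float
    prop_later: float
    odds_ratio: float
    p_value: float
    applicable: bool


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

def gene_noise_z(f: Sequence[float], s: Sequence[int], t: Sequence[int]) -> NoiseEstimate:
    """Noise of the fragment-score mean for one gene, and its z statistic.

    Per fragment: sqrt(1/(1+s) + 1/(1+t)) / ln 2 (Poisson counting noise of
    the log2 ratio).  Gene noise: sqrt(sum of squared fragment noises) / n.
    z = mean(f) / gene_noise; under pure counting noise z is approximately
    standard normal.
    """
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if f.size == 0:
        raise ValueError("need at least one covering fragment")
    frag_noise = np.sqrt(1.0 / (1.0 + s) + 1.0 / (1.0 + t)) / LN2
    gene_noise = float(np.sqrt(np.sum(frag_noise**2)) / f.size)
    z = float(f.mean() / gene_noise)
    return NoiseEstimate(tuple(frag_noise.tolist()), gene_noise, z)


def consistency_test(
    gene_f: Sequence[float],
    all_f: Sequence[float],
    gene_score: float,
    thresholds: Thresholds = Thresholds(),
) -> Tuple[bool, float]:
    """Do the covering fragments agree on the effect?

    With >= 2 fragments: two-tailed one-sample t-test of the covering
    fragment scores against a reference r, where r is the mean of *all*
    fragment scores in the experiment if that mean has the same sign as the
    gene score (guarding against miscentering, and slightly more stringent),
    else 0.  Pass iff p < 0.05.  With a single fragment the t-test is
    impossible; the fragment passes iff |f| is in the top 1% of |f| for the
    experiment (p reported as NaN).

    Degenerate case: >= 2 identical fragment scores (zero variance) pass
    with p = 0 when their mean differs from r, else fail with p = 1.
    """
    gene_f = np.asarray(gene_f, dtype=float)
    all_f = np.asarray(all_f, dtype=float)
    if gene_f.size == 0:
        raise ValueError("need at least one covering fragment")
    if gene_f.size == 1:
        cutoff = float(np.quantile(np.abs(all_f), 1.0 - thresholds.top_fraction))
        return bool(abs(gene_f[0]) >= cutoff), float("nan")
    overall = float(all_f.mean())
    reference = overall if np.sign(overall) == np.sign(gene_score) else 0.0
    if float(gene_f.std(ddof=1)) == 0.0:
        p = 0.0 if gene_f.mean() != reference else 1.0
    else:
        p = float(stats.ttest_1samp(gene_f, popmean=reference).pvalue)
    return bool(p < thresholds.max_p), p


# ---------------------------------------------------------------------------
# Effect calling
# ---------------------------------------------------------------------------

def call_reliable(
    gene_scores: pd.DataFrame,
    fragment_scores: pd.DataFrame,
    experiment_id: str,
    thresholds: Thresholds = Thresholds(),
    score_column: str = "score",
) -> pd.DataFrame:
    """Apply the three filters to every scored gene of one experiment.

    ``gene_scores`` is the frame from :func:`~dubseq.scoring.compute_gene_scores_nnls`
    (``score_column`` selects which score feeds the magnitude filter, the
    regression score by default); ``fragment_scores`` is the experiment's
    fragment-score frame (columns s, t, f).  The noise filter always uses
    the fragment-score mean, per its defining formula.
    """
    all_f = fragment_scores["f"].to_numpy(dtype=float)
    records = []
    for gene_id, row in gene_scores.iterrows():
        frag_ids = list(row["fragment_ids"])
        sub = fragment_scores.loc[frag_ids]
        score = float(row[score_column])
        passes_magnitude = abs(score) >= thresholds.min_abs_score
        passes_consistency, p = consistency_test(
            sub["f"].to_numpy(), all_f, score, thresholds
        )
        noise = gene_noise_z(
            sub["f"].to_numpy(), sub["s"].to_numpy(), sub["t"].to_numpy()
        )
        passes_noise = abs(noise.z) >= thresholds.min_abs_z
        records.append(
            {
                "gene_id": gene_id,
                "experiment_id": experiment_id,
                "score": score,
                "score_mean": float(row["score_mean"]),
                "p": p,
                "z": noise.z,
                "n_fragments": int(row["n_fragments"]),
                "passes_magnitude": passes_magnitude,
                "passes_consistency": passes_consistency,
                "passes_noise": passes_noise,
                "reliable": passes_magnitude and passes_consistency and passes_noise,
            }
        )
    return pd.DataFrame(records)


def call_high_confidence(
    calls: pd.DataFrame,
    compound_map: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Upgrade reliable effects to high confidence.

    ``calls`` concatenates :func:`call_reliable` frames across experiments.
    A reliable single-fragment effect needs support from *another* experiment
    of the same compound with |score| >= 2 (secondary mutations on one
    plasmid would otherwise masquerade as gene effects).
    """
    calls = calls.copy()
    calls["compound"] = calls["experiment_id"].map(lambda e: compound_map.get(e, e))
    high = []
    for _, row in calls.iterrows():
        if not row["reliable"]:
            high.append(False)
            continue
        if row["n_fragments"] >= 2:
            high.append(True)
            continue
        others = calls[
            (calls["gene_id"] == row["gene_id"])
            & (calls["compound"] == row["compound"])
            & (calls["experiment_id"] != row["experiment_id"])
        ]
        high.append(bool((others["score"].abs() >= thresholds.min_abs_score).any()))
    calls["high_confidence"] = high
    return calls


def replicate_consistency(
    calls: pd.DataFrame,
    replicate_pairs: Sequence[Tuple[str, str]],
    thresholds: Thresholds = Thresholds(),
) -> float:
    """Fraction of filtered (reliable) effects consistent in the replicate.

    For each reliable effect in experiment A of a pair, the effect is
    consistent iff experiment B scored the gene with |score| >= 1.5 and the
    same sign.  Both orientations of each pair are evaluated.
    """
    n_effects = 0
    n_consistent = 0
    by_exp = {e: g.set_index("gene_id") for e, g in calls.groupby("experiment_id")}
    for a, b in replicate_pairs:
        for first, second in ((a, b), (b, a)):
            if first not in by_exp or second not in by_exp:
                continue
            effects = by_exp[first][by_exp[first]["reliable"]]
            partner = by_exp[second]
            for gene_id, row in effects.iterrows():
                n_effects += 1
                if gene_id not in partner.index:
                    continue
                other = float(partner.at[gene_id, "score"])
                if (
                    abs(other) >= thresholds.replicate_min_abs_score
                    and np.sign(other) == np.sign(row["score"])
                ):
                    n_consistent += 1
    if n_effects == 0:
        return float("nan")
    return n_consistent / n_effects


def expected_false_positives(n_genes: int, z_threshold: float) -> float:
    """Expected count of |z| >= threshold calls under the standard-normal null."""
    if z_threshold < 0:
        raise ValueError("z_threshold must be >= 0")
    return float(n_genes) * 2.0 * float(stats.norm.sf(z_threshold))


# ---------------------------------------------------------------------------
# Shuffle FDR
# ---------------------------------------------------------------------------

def _call_from_mean_scores(
    scores: pd.DataFrame,
    coverage: CoverageMatrix,
    experiment_id: str,
    thresholds: Thresholds,
) -> pd.DataFrame:
    """Effect calls where the mean score plays the role of the gene score."""
    present = [b for b in coverage.fragment_barcodes if b in scores.index]
    cov = coverage.restrict_fragments(present)
    A = cov.matrix.astype(float)
    covered = A.sum(axis=0) > 0
    A_red = A[:, covered]
    gene_ids = [g for g, c in zip(cov.gene_ids, covered) if c]
    f = scores.loc[present, "f"].to_numpy(dtype=float)
    n_frag = A_red.sum(axis=0)
    mean = (A_red.T @ f) / n_frag
    frame = pd.DataFrame(
        {
            "score": mean,
            "score_mean": mean,
            "n_fragments": n_frag.astype(int),
            "fragment_ids": [
                tuple(np.asarray(present, dtype=object)[A_red[:, j] > 0])
                for j in range(A_red.shape[1])
            ],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return call_reliable(frame, scores, experiment_id, thresholds)


def estimate_fdr_by_shuffling(
    scores_by_experiment: Mapping[str, pd.DataFrame],
    coverage: CoverageMatrix,
    compound_map: Mapping[str, str],
    n_shuffles: int = 10,
    seed: int = 0,
    thresholds: Thresholds = Thresholds(),
) -> FdrEstimate:
    """Estimate the FDR of high-confidence calls by barcode shuffling.

    The genuine data is scored with the regression gene scores and the full
    calling scheme to obtain the actual high-confidence count.  Each shuffle
    permutes the barcode -> fragment assignment uniformly at random (the
    fragments' gene-coverage structure is untouched; only which barcode's
    counts sit on which fragment changes), recomputes *mean* gene scores and
    applies the same calling.  The mean-score route deliberately matches the
    shuffle's null: any residual structure it finds is pure noise.
    """
    rng = np.random.default_rng(seed)
    actual_calls = []
    for exp, scores in scores_by_experiment.items():
        gene_scores = compute_gene_scores_nnls(scores, coverage)
        actual_calls.append(call_reliable(gene_scores, scores, exp, thresholds))
    actual = call_high_confidence(pd.concat(actual_calls, ignore_index=True),
                                  compound_map, thresholds)
    actual_count = int(actual["high_confidence"].sum())

    n_ref = len(coverage.fragment_barcodes)
    shuffled_counts = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n_ref)
        shuffled = CoverageMatrix(
            coverage.matrix[perm],
            list(coverage.fragment_barcodes),
            list(coverage.gene_ids),
        )
        calls = []
        for exp, scores in scores_by_experiment.items():
            calls.append(_call_from_mean_scores(scores, shuffled, exp, thresholds))
        combined = call_high_confidence(
            pd.concat(calls, ignore_index=True), compound_map, thresholds
        )
        shuffled_counts.append(int(combined["high_confidence"].sum()))
    return FdrEstimate(
        n_shuffles=n_shuffles,
        shuffled_counts=shuffled_counts,
        actual_count=actual_count,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Operon position comparison
# ---------------------------------------------------------------------------

def operon_position_comparison(
    has_effect: Mapping[str, bool],
    operons: pd.DataFrame,
) -> OperonComparison:
    """Are first-in-transcript genes more likely to show effects?

    ``has_effect`` maps gene_id -> whether the gene has a high-confidence
    effect in any experiment; ``operons`` is the table from
    :func:`~dubseq.io.read_operons` (gene_id, position).  Only genes present
    in both inputs enter the 2x2 table, which is tested with Fisher's exact
    test (two-sided).
    """
    rows = operons[operons["gene_id"].isin(has_effect.keys())]
    first = rows[rows["position"] == "first"]["gene_id"]
    later = rows[rows["position"] == "later"]["gene_id"]
    fe = int(sum(has_effect[g] for g in first))
    fn = len(first) - fe
    le = int(sum(has_effect[g] for g in later))
    ln_ = len(later) - le
    table = ((fe, fn), (le, ln_))
    if len(first) == 0 or len(later) == 0:
        return OperonComparison(table, float("nan"), float("nan"),
                                float("nan"), float("nan"), applicable=False)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return OperonComparison(
        table=table,
        prop_first=fe / len(first),
        prop_later=le / len(later),
        odds_ratio=float(odds),
        p_value=float(p),
        applicable=True,
    )
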