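"""Independent oracles used to check the package's algorithms.

Everything here is deliberately naive — exhaustive scans and grid
enumeration — so it shares no code path with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def scan_barcode_offsets(sequence: str, spec) -> list[int]:
    """All offsets where both anchors match exactly (no window applied)."""
    hits = []
    L = spec.barcode_length
    for off in range(9, len(sequence) - L - 9 + 1):
        if (
            sequence[off - 9 : off] == spec.upstream_anchor
            and sequence[off + L : off + L + 9] == spec.downstream_anchor
        ):
            hits.append(off)
    return hits


def genome_occurrences(tail: str, genome: dict[str, str]) -> list[tuple[str, int, str]]:
    """Every exact occurrence of tail (either strand) by full scan."""
    out = []
    for contig, seq in genome.items():
        for query, strand in ((tail, "+"), (revcomp(tail), "-")):
            start = seq.find(query)
            while start != -1:
                out.append((contig, start, strand))
                start = seq.find(query, start + 1)
    return out


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def one_off_filter_bruteforce(counts: dict[str, int]) -> dict[str, int]:
    """Quadratic pairwise-Hamming version of the one-off barcode filter."""
    kept = {}
    for bc, c in counts.items():
        rivals = [
            c2
            for bc2, c2 in counts.items()
            if bc2 != bc and len(bc2) == len(bc) and hamming(bc, bc2) == 1
        ]
        if not rivals or c >= 2 * max(rivals):
            kept[bc] = c
    return kept


def nnls_grid(A: np.ndarray, f: np.ndarray, upper: float = 6.0,
              step: float = 0.01) -> np.ndarray:
    """Nonnegative grid minimizer of ||A g - f||^2.

    Exhaustive over a full grid at step 0.01 for <= 2 genes; for 3-4 genes
    the full grid is walked coarse-to-fine (0.5 -> 0.05 -> 0.01), each stage
    enumerating the complete grid of its resolution around the previous
    optimum.  Evaluation is vectorised but the search itself is pure
    enumeration.
    """
    A = np.asarray(A, dtype=float)
    f = np.asarray(f, dtype=float)
    n = A.shape[1]

    def best_on(axes):
        grids = np.meshgrid(*axes, indexing="ij")
        G = np.stack([g.ravel() for g in grids], axis=1)
        obj = np.sum((G @ A.T - f) ** 2, axis=1)
        return G[int(np.argmin(obj))]

    if n <= 2:
        axis = np.arange(0.0, upper + step / 2, step)
        return best_on([axis] * n)
    best = best_on([np.arange(0.0, upper + 0.25, 0.5)] * n)
    for radius, s in ((0.5, 0.05), (0.05, step)):
        axes = [
            np.arange(max(0.0, c - radius), c + radius + s / 2, s) for c in best
        ]
        best = best_on(axes)
    return best


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration over fixed margins."""
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x: int) -> float:
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(n, col1)
        )

    observed = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(x)
        if p <= observed * (1 + 1e-9):
            total += p
    return min(1.0, total)
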