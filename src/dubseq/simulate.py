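"""Synthetic genomes, barcoded fragment libraries, reads and fitness counts.

Everything the pipeline consumes can be generated here with a known truth
table, so each stage can be audited exactly: a random genome with
non-overlapping genes, a shotgun fragment library with unique UP/DOWN
barcode pairs, reads for the three assay layouts (barcode-pair,
barcode-genome-junction, barcode-count) with configurable base errors and
chimeric-PCR reads, and pooled-growth count data in which each gene's
injected log2 effect beta multiplies the abundance of every fragment that
fully covers it by 2**beta.

Counts follow a Poisson model around a log-normal library-abundance
baseline — the simplest generative model consistent with the Poisson
counting-noise formula used by the effect-calling filters.  All draws are
reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .barcodes import FlankSpec
from .counting import CountMatrix
from .library import ReferenceFragment, revcomp

__all__ = [
    "SimConfig",
    "TruthTables",
    "bpseq_flank_specs",
    "bagseq_flank_spec",
    "barseq_flank_spec",
    "simulate_genome_and_genes",
    "simulate_library",
    "simulate_reads",
    "simulate_fitness_counts",
    "make_design",
    "default_effects",
]

_BASES = np.array(list("ACGT"))

# Vector context written into every simulated read.  The pipeline receives
# these through the FlankSpec helpers below; they are configuration, not
# biology.
UP_LEFT = "CAGCGTACG"
UP_RIGHT = "AGAGACCTC"
DOWN_LEFT = "GTCGACCTG"
DOWN_RIGHT = "GATGTCCAC"
READ_PREFIX = "TTCT"
PAIR_SPACER = "ACGTACGTAC"

_STAGE_GENOME = 11
_STAGE_LIBRARY = 23
_STAGE_READS = 37
_STAGE_COUNTS = 53


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic library.

    Defaults describe a desk-scale library: a 50 kb genome with 40 genes and
    500 fragments whose lengths are Normal(2600, 800) nt clamped to the
    100-6000 nt cloning window (real shotgun libraries of this design have a
    ~2.6 kb mean insert), sequenced to a mean depth of 100 reads per
    fragment per sample.
    """

    genome_length: int = 50_000
    n_genes: int = 40
    gene_length_range: Tuple[int, int] = (400, 1200)
    n_fragments: int = 500
    fragment_mean: float = 2600.0
    fragment_sd: float = 800.0
    min_fragment: int = 100
    max_fragment: int = 6000
    barcode_length: int = 20
    error_rate: float = 0.0
    base_quality: int = 30
    chimera_rate: float = 0.0
    reads_per_pair: int = 10
    tail_length: int = 60
    depth: float = 100.0  # mean reads per fragment per sample
    abundance_sigma: float = 0.5  # log-normal spread of library abundances
    effects: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.n_genes, self.n_fragments) <= 0:
            raise ValueError("sizes must be positive")
        for rate in (self.error_rate, self.chimera_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be within [0, 1]")


@dataclass
class TruthTables:
    """Ground truth behind one simulated library."""

    config: SimConfig
    genome: dict[str, str]
    genes: pd.DataFrame  # gene_id, contig, start, end, strand
    fragments: pd.DataFrame  # up, down, contig, start, end, orientation
    effects: dict[str, float]

    def reference_fragments(self) -> list[ReferenceFragment]:
        return [
            ReferenceFragment(r.up, r.down, r.contig, int(r.start), int(r.end))
            for r in self.fragments.itertuples()
        ]

    def coverage(self) -> np.ndarray:
        """Binary fragments x genes complete-coverage truth matrix."""
        g_start = self.genes["start"].to_numpy()
        g_end = self.genes["end"].to_numpy()
        g_contig = self.genes["contig"].to_numpy()
        A = np.zeros((len(self.fragments), len(self.genes)), dtype=np.int8)
        for i, r in enumerate(self.fragments.itertuples()):
            A[i] = (g_contig == r.contig) & (g_start >= r.start) & (g_end <= r.end)
        return A

    def expected_fragment_fitness(self) -> np.ndarray:
        """Sum over covered genes of the injected effects (log2 scale)."""
        beta = np.array(
            [self.effects.get(g, 0.0) for g in self.genes["gene_id"]], dtype=float
        )
        return self.coverage() @ beta


# ---------------------------------------------------------------------------
# Flank specs matching the simulated read layouts
# ---------------------------------------------------------------------------

def bpseq_flank_specs(barcode_length: int = 20) -> Tuple[FlankSpec, FlankSpec]:
    """(UP spec, DOWN spec) for barcode-pair reads."""
    up_start = len(READ_PREFIX) + 9
    down_start = up_start + barcode_length + 9 + len(PAIR_SPACER) + 9
    up = FlankSpec(UP_LEFT, UP_RIGHT, up_start, barcode_length=barcode_length)
    down = FlankSpec(DOWN_LEFT, DOWN_RIGHT, down_start, barcode_length=barcode_length)
    return up, down


def bagseq_flank_spec(tag: str = "up", barcode_length: int = 20) -> FlankSpec:
    left, right = (UP_LEFT, UP_RIGHT) if tag == "up" else (DOWN_LEFT, DOWN_RIGHT)
    return FlankSpec(left, right, len(READ_PREFIX) + 9, barcode_length=barcode_length)


def barseq_flank_spec(tag: str = "up", barcode_length: int = 20) -> FlankSpec:
    return bagseq_flank_spec(tag, barcode_length)


# ---------------------------------------------------------------------------
# Genome, genes, library
# ---------------------------------------------------------------------------

def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def simulate_genome_and_genes(config: SimConfig) -> Tuple[dict[str, str], pd.DataFrame]:
    """A random genome plus non-overlapping gene intervals, gap-separated."""
    rng = _rng(config, _STAGE_GENOME)
    genome = {"contig1": _random_seq(rng, config.genome_length)}
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    total = int(lengths.sum())
    slack = config.genome_length - total
    if slack < config.n_genes + 1:
        raise ValueError(
            f"cannot place {config.n_genes} genes totalling {total} nt in a "
            f"{config.genome_length} nt genome"
        )
    # distribute the slack into n_genes + 1 gaps (each >= 1 nt)
    cuts = np.sort(rng.choice(slack - 1, size=config.n_genes, replace=False)) + 1
    gaps = np.diff(np.concatenate([[0], cuts, [slack]]))
    rows = []
    pos = 0
    for i, (gap, length) in enumerate(zip(gaps[:-1], lengths)):
        pos += int(gap)
        rows.append(
            {
                "gene_id": f"g{i + 1:04d}",
                "contig": "contig1",
                "start": pos,
                "end": pos + int(length),
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        pos += int(length)
    return genome, pd.DataFrame(rows)


def _unique_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = _random_seq(rng, length)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_library(
    config: SimConfig,
    genome: dict[str, str],
    genes: pd.DataFrame,
) -> TruthTables:
    """Draw the fragment library and assign unique barcode pairs.

    Fragment lengths ~ Normal(mean, sd) clamped to the cloning window, at
    uniform positions; each fragment is cloned in a random orientation
    (which end carries the UP barcode), as a real shotgun ligation would.
    """
    rng = _rng(config, _STAGE_LIBRARY)
    contig = next(iter(genome))
    glen = len(genome[contig])
    lengths = np.clip(
        rng.normal(config.fragment_mean, config.fragment_sd, size=config.n_fragments),
        config.min_fragment,
        min(config.max_fragment, glen),
    ).astype(int)
    starts = rng.integers(0, glen - lengths + 1)
    ups = _unique_barcodes(rng, config.n_fragments, config.barcode_length)
    downs = _unique_barcodes(rng, config.n_fragments, config.barcode_length)
    orientation = np.where(rng.random(config.n_fragments) < 0.5, "+", "-")
    fragments = pd.DataFrame(
        {
            "fragment_id": [f"f{i + 1:05d}" for i in range(config.n_fragments)],
            "up": ups,
            "down": downs,
            "contig": contig,
            "start": starts,
            "end": starts + lengths,
            "orientation": orientation,
        }
    )
    effects = dict(config.effects) if config.effects else {}
    unknown = set(effects) - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"effects refer to unknown genes: {sorted(unknown)}")
    return TruthTables(
        config=config, genome=genome, genes=genes, fragments=fragments, effects=effects
    )


def default_effects(genes: pd.DataFrame, n_effects: int = 5) -> dict[str, float]:
    """Spread a few large positive effects (beta in {2, 3, 4}) across the genome."""
    ids = genes["gene_id"].tolist()
    step = max(1, len(ids) // n_effects)
    chosen = [ids[(i * step + step // 2) % len(ids)] for i in range(n_effects)]
    betas = [2.0, 3.0, 4.0, 2.0, 3.0]
    return {g: betas[i % len(betas)] for i, g in enumerate(chosen)}


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _finish_read(
    rng: np.random.Generator, config: SimConfig, read_id: str, seq: str
) -> Tuple[str, str, list[int]]:
    seq = _apply_errors(rng, seq, config.error_rate)
    return read_id, seq, [config.base_quality] * len(seq)


def _junction_tails(truth: TruthTables, row) -> Tuple[str, str]:
    """(UP tail, DOWN tail) for one fragment, honouring its orientation."""
    seq = truth.genome[row.contig]
    n = truth.config.tail_length
    left = seq[row.start : row.start + min(n, row.end - row.start)]
    right_raw = seq[max(row.start, row.end - n) : row.end]
    right = revcomp(right_raw)
    # '+' orientation: UP barcode sits at the left (lower-coordinate) end.
    return (left, right) if row.orientation == "+" else (right, left)


def simulate_reads(
    truth: TruthTables,
    assay: str,
) -> list[Tuple[str, str, list[int]]]:
    """Reads for one assay: 'bpseq', 'bagseq_up', 'bagseq_down'.

    Barcode-pair reads carry both barcodes in one read; at ``chimera_rate``
    a read pairs the UP barcode of one fragment with the DOWN barcode of
    another (labelled ``chimera=1`` in the read name, for truth audits).
    Junction reads carry one barcode followed by the adjacent genomic tail.
    """
    config = truth.config
    rng = _rng(config, _STAGE_READS + {"bpseq": 0, "bagseq_up": 1, "bagseq_down": 2}[assay])
    reads = []
    if assay == "bpseq":
        n_frag = len(truth.fragments)
        for idx, row in enumerate(truth.fragments.itertuples()):
            for r in range(config.reads_per_pair):
                if rng.random() < config.chimera_rate and n_frag > 1:
                    other = int(rng.integers(0, n_frag - 1))
                    if other >= idx:
                        other += 1
                    down = truth.fragments["down"].iloc[other]
                    label = 1
                else:
                    down = row.down
                    label = 0
                seq = (
                    READ_PREFIX + UP_LEFT + row.up + UP_RIGHT
                    + PAIR_SPACER + DOWN_LEFT + down + DOWN_RIGHT + "AC"
                )
                reads.append(
                    _finish_read(
                        rng, config,
                        f"bp_{row.fragment_id}_{r}|chimera={label}", seq,
                    )
                )
    elif assay in ("bagseq_up", "bagseq_down"):
        tag = "up" if assay == "bagseq_up" else "down"
        left, right = (UP_LEFT, UP_RIGHT) if tag == "up" else (DOWN_LEFT, DOWN_RIGHT)
        for row in truth.fragments.itertuples():
            up_tail, down_tail = _junction_tails(truth, row)
            tail = up_tail if tag == "up" else down_tail
            barcode = row.up if tag == "up" else row.down
            seq = READ_PREFIX + left + barcode + right + tail
            for r in range(config.reads_per_pair):
                reads.append(
                    _finish_read(rng, config, f"bag_{tag}_{row.fragment_id}_{r}", seq)
                )
    else:
        raise ValueError(f"unknown assay {assay!r}")
    return reads


def simulate_barseq_reads(
    truth: TruthTables, counts: pd.Series
) -> list[Tuple[str, str, list[int]]]:
    """Barcode-count reads for one sample from a per-barcode count vector."""
    config = truth.config
    rng = _rng(config, _STAGE_READS + 3)
    reads = []
    for barcode, n in counts.items():
        seq = READ_PREFIX + UP_LEFT + barcode + UP_RIGHT + "AC"
        for r in range(int(n)):
            reads.append(_finish_read(rng, config, f"bs_{barcode}_{r}", seq))
    return reads


# ---------------------------------------------------------------------------
# Fitness counts
# ---------------------------------------------------------------------------

def make_design(
    conditions: Sequence[str] = ("condA",),
    n_time_zero: int = 2,
    n_replicates: int = 2,
    set_id: str = "set1",
) -> pd.DataFrame:
    """A single-set design: shared time-zero samples plus per-condition replicates."""
    rows = [
        {
            "sample_id": f"T0_{i + 1}",
            "set_id": set_id,
            "condition": "Time0",
            "is_time_zero": True,
            "replicate_group": "T0",
        }
        for i in range(n_time_zero)
    ]
    for cond in conditions:
        for r in range(n_replicates):
            rows.append(
                {
                    "sample_id": f"{cond}_r{r + 1}",
                    "set_id": set_id,
                    "condition": cond,
                    "is_time_zero": False,
                    "replicate_group": cond,
                }
            )
    return pd.DataFrame(rows)


def simulate_fitness_counts(
    truth: TruthTables,
    design: pd.DataFrame,
) -> CountMatrix:
    """Pooled-growth read counts for every sample of the design.

    Each fragment gets a log-normal baseline abundance scaled so the mean
    depth per fragment equals ``config.depth``.  Time-zero samples draw
    Poisson counts from that baseline.  Condition samples multiply each
    fragment's abundance by 2**(sum of covered genes' effects), rescale to
    the same total depth (a pooled assay measures relative abundance), and
    draw Poisson counts.
    """
    config = truth.config
    rng = _rng(config, _STAGE_COUNTS)
    n = len(truth.fragments)
    baseline = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    baseline *= config.depth * n / baseline.sum()
    fold = 2.0 ** truth.expected_fragment_fitness()
    columns = {}
    for row in design.itertuples():
        if row.is_time_zero:
            lam = baseline
        else:
            boosted = baseline * fold
            lam = boosted * (config.depth * n / boosted.sum())
        columns[row.sample_id] = rng.poisson(lam)
    counts = pd.DataFrame(columns, index=truth.fragments["up"].tolist())
    totals = counts.sum(axis=0)
    return CountMatrix(
        counts=counts,
        totals=totals,
        usable=totals.copy(),
        unmapped=pd.Series(0, index=counts.columns),
    )
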