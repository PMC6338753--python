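import pytest

from dubseq.barcodes import FlankSpec
from dubseq.simulate import (
    SimConfig,
    default_effects,
    make_design,
    simulate_fitness_counts,
    simulate_genome_and_genes,
    simulate_library,
)

# a compact spec used across the unit tests
UP = "CAGCGTACG"
DOWN = "AGAGACCTC"


@pytest.fixture
def spec() -> FlankSpec:
    return FlankSpec(UP, DOWN, expected_start=13)


def make_read(barcode: str, spec: FlankSpec, shift: int = 0, tail: str = "",
              quality: int = 30):
    """Construct a read placing ``barcode`` at expected_start + shift."""
    start = spec.expected_start + shift
    if start < 9:
        raise ValueError("shift leaves no room for the upstream anchor")
    pad = ("TCTG" * 8)[: start - 9]
    seq = pad + spec.upstream_anchor + barcode + spec.downstream_anchor + tail
    return seq, [quality] * len(seq)


@pytest.fixture(scope="session")
def small_truth():
    """An 80-fragment, 15-gene library with three injected effects."""
    cfg = SimConfig(genome_length=20_000, n_genes=15, n_fragments=80, seed=7)
    genome, genes = simulate_genome_and_genes(cfg)
    effects = default_effects(genes, 3)
    cfg = SimConfig(genome_length=20_000, n_genes=15, n_fragments=80, seed=7,
                    effects=effects)
    return simulate_library(cfg, genome, genes)


@pytest.fixture(scope="session")
def small_counts(small_truth):
    design = make_design()
    return simulate_fitness_counts(small_truth, design), design
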