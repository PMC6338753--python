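"""Per-sample barcode counting and assembly of the sample x barcode matrix.

Counts are taken on the UP barcodes by default (the two barcodes of a pair
give near-identical fitness readouts, so one suffices); ``tag='down'`` is
available for the UP/DOWN concordance check.  No depth normalisation happens
here — normalisation is entirely inside the fitness log-ratio and its median
centering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Tuple

import pandas as pd

from .barcodes import BarcodeCounts, FlankSpec, filter_one_off_barcodes, tally_barcodes
from .io import ConfigurationError, validate_design
from .library import ReferenceFragment

__all__ = ["CountMatrix", "count_sample", "assemble_count_matrix"]


@dataclass
class CountMatrix:
    """Read counts per reference barcode (rows) and sample (columns).

    ``totals``/``usable`` carry per-sample read accounting; ``unmapped`` is
    the number of usable reads whose barcode is not in the reference set.
    Invariant: column sums + unmapped == usable reads per sample.
    """

    counts: pd.DataFrame
    totals: pd.Series
    usable: pd.Series
    unmapped: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)


def count_sample(
    reads: Iterable[Tuple[str, str, Sequence[int]]],
    spec: FlankSpec,
) -> BarcodeCounts:
    """Tally barcodes for one sample's reads, then apply the one-off filter."""
    return filter_one_off_barcodes(tally_barcodes(reads, spec))


def assemble_count_matrix(
    sample_counts: Mapping[str, BarcodeCounts],
    reference: Sequence[ReferenceFragment],
    design: pd.DataFrame,
    tag: str = "up",
) -> CountMatrix:
    """Assemble the count matrix over reference barcodes.

    Barcodes observed in a sample but absent from the reference are summed
    into that sample's unmapped tally; reference barcodes unseen in a sample
    get count 0.  All design samples must be present in ``sample_counts``.
    """
    design = validate_design(design)
    if tag not in ("up", "down"):
        raise ValueError("tag must be 'up' or 'down'")
    wanted = list(design["sample_id"])
    missing = [s for s in wanted if s not in sample_counts]
    if missing:
        raise ConfigurationError(f"missing counts for design samples: {missing}")

    ref_barcodes = [getattr(f, tag) for f in reference]
    if len(set(ref_barcodes)) != len(ref_barcodes):
        raise ValueError("reference fragments must have unique barcodes")
    ref_set = set(ref_barcodes)

    counts = pd.DataFrame(0, index=ref_barcodes, columns=wanted, dtype=int)
    totals, usable, unmapped = {}, {}, {}
    for sample in wanted:
        bc = sample_counts[sample]
        totals[sample] = bc.total_reads
        usable[sample] = bc.usable_reads
        off_target = 0
        for barcode, n in bc.counts.items():
            if barcode in ref_set:
                counts.at[barcode, sample] = n
            else:
                off_target += n
        unmapped[sample] = off_target
    return CountMatrix(
        counts=counts,
        totals=pd.Series(totals, dtype=int),
        usable=pd.Series(usable, dtype=int),
        unmapped=pd.Series(unmapped, dtype=int),
    )
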