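"""Locating random DNA barcodes inside sequencing reads.

A barcode is a stretch of random nucleotides (20 nt by default) embedded in a
read between two fixed 9-nt anchor sequences that come from the vector.  A
barcode is accepted only when both anchors match exactly at an offset close to
the expected position, every barcode base is a definite call (A/C/G/T) and
every barcode base passes a Phred-quality gate.  Sequencing errors inside the
barcode itself produce spurious one-mismatch neighbours of real barcodes;
:func:`filter_one_off_barcodes` removes those by a 2x relative-frequency rule.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "FlankSpec",
    "ExtractedBarcode",
    "BarcodeCounts",
    "MalformedReadError",
    "extract_barcode",
    "extract_barcode_with_tail",
    "tally_barcodes",
    "filter_one_off_barcodes",
    "hamming1_neighbors",
]

_BASES = "ACGT"
_ANCHOR_LEN = 9


class MalformedReadError(ValueError):
    """Raised for structurally invalid reads (sequence/quality length mismatch)."""


@dataclass(frozen=True)
class FlankSpec:
    """Where to look for a barcode and how strictly to accept it.

    Parameters
    ----------
    upstream_anchor, downstream_anchor:
        The exact 9-nt vector sequences immediately 5' and 3' of the barcode.
    expected_start:
        0-based read offset where the barcode is expected to begin.
    max_shift:
        The barcode may start up to this many nt away from ``expected_start``.
    barcode_length:
        Number of random nt in the barcode.
    min_base_quality:
        Minimum Phred score required for every barcode base (Q20 ~ 1% error).
    min_tail_length:
        Minimum length of the genomic tail downstream of the downstream
        anchor; only used by :func:`extract_barcode_with_tail`.
    """

    upstream_anchor: str
    downstream_anchor: str
    expected_start: int
    max_shift: int = 2
    barcode_length: int = 20
    min_base_quality: int = 20
    min_tail_length: int = 15

    def __post_init__(self) -> None:
        for name in ("upstream_anchor", "downstream_anchor"):
            anchor = getattr(self, name)
            if len(anchor) != _ANCHOR_LEN or any(b not in _BASES for b in anchor):
                raise ValueError(
                    f"{name} must be exactly {_ANCHOR_LEN} nt over A/C/G/T, got {anchor!r}"
                )
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if self.expected_start < _ANCHOR_LEN:
            raise ValueError(
                "expected_start must leave room for the upstream anchor "
                f"(>= {_ANCHOR_LEN})"
            )

    def candidate_offsets(self) -> list[int]:
        """Allowed barcode start offsets, nearest to ``expected_start`` first.

        Ties (equidistant shifts) are broken toward the smaller offset.
        """
        offsets = range(
            self.expected_start - self.max_shift, self.expected_start + self.max_shift + 1
        )
        return sorted(
            (o for o in offsets if o >= _ANCHOR_LEN),
            key=lambda o: (abs(o - self.expected_start), o),
        )


@dataclass(frozen=True)
class ExtractedBarcode:
    """A barcode pulled out of one read.

    ``tail`` is the candidate genomic fragment: everything 3' of the
    downstream anchor.  It is only populated by
    :func:`extract_barcode_with_tail`.
    """

    sequence: str
    read_id: str
    offset: int
    tail: Optional[str] = None


@dataclass
class BarcodeCounts:
    """Barcode -> read-count table with read-accounting totals."""

    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    usable_reads: int = 0

    def __post_init__(self) -> None:
        if self.usable_reads != sum(self.counts.values()):
            raise ValueError("usable_reads must equal the sum of counts")
        if self.usable_reads > self.total_reads:
            raise ValueError("usable_reads cannot exceed total_reads")


def _check_read(sequence: str, qualities: Sequence[int]) -> None:
    if len(sequence) != len(qualities):
        raise MalformedReadError(
            f"sequence length {len(sequence)} != quality length {len(qualities)}"
        )


def _match_at(
    sequence: str, qualities: Sequence[int], spec: FlankSpec, offset: int
) -> bool:
    """True iff a fully valid barcode starts at ``offset``."""
    up_start = offset - _ANCHOR_LEN
    bc_end = offset + spec.barcode_length
    if bc_end + _ANCHOR_LEN > len(sequence):
        return False
    if sequence[up_start:offset] != spec.upstream_anchor:
        return False
    if sequence[bc_end : bc_end + _ANCHOR_LEN] != spec.downstream_anchor:
        return False
    barcode = sequence[offset:bc_end]
    if any(b not in _BASES for b in barcode):
        return False
    if min(qualities[offset:bc_end]) < spec.min_base_quality:
        return False
    return True


def extract_barcode(
    sequence: str,
    qualities: Sequence[int],
    spec: FlankSpec,
    read_id: str = "",
) -> Optional[ExtractedBarcode]:
    """Extract the barcode from one read, or ``None`` if no valid match.

    The barcode start is searched within ``expected_start +/- max_shift``;
    at each candidate offset both 9-nt anchors must match exactly and every
    barcode base must be A/C/G/T with quality >= ``min_base_quality``.  The
    offset closest to ``expected_start`` wins (tie: smaller offset).
    """
    _check_read(sequence, qualities)
    for offset in spec.candidate_offsets():
        if _match_at(sequence, qualities, spec, offset):
            return ExtractedBarcode(
                sequence=sequence[offset : offset + spec.barcode_length],
                read_id=read_id,
                offset=offset,
            )
    return None


def extract_barcode_with_tail(
    sequence: str,
    qualities: Sequence[int],
    spec: FlankSpec,
    read_id: str = "",
) -> Optional[ExtractedBarcode]:
    """Like :func:`extract_barcode` but also require a genomic tail.

    The tail is everything 3' of the downstream anchor and must be at least
    ``spec.min_tail_length`` nt (too-short tails cannot be mapped reliably),
    otherwise the read is rejected.
    """
    _check_read(sequence, qualities)
    for offset in spec.candidate_offsets():
        if not _match_at(sequence, qualities, spec, offset):
            continue
        tail_start = offset + spec.barcode_length + _ANCHOR_LEN
        tail = sequence[tail_start:]
        if len(tail) < spec.min_tail_length:
            return None
        return ExtractedBarcode(
            sequence=sequence[offset : offset + spec.barcode_length],
            read_id=read_id,
            offset=offset,
            tail=tail,
        )
    return None


def tally_barcodes(
    reads: Iterable[Tuple[str, str, Sequence[int]]],
    spec: FlankSpec,
) -> BarcodeCounts:
    """Count extracted barcodes over a stream of ``(read_id, seq, quals)``.

    ``total_reads`` counts every record seen; ``usable_reads`` counts those
    that yielded a barcode.  A malformed record raises
    :class:`MalformedReadError` annotated with its (0-based) index.
    """
    counts: Counter[str] = Counter()
    total = 0
    for idx, (read_id, sequence, qualities) in enumerate(reads):
        total += 1
        try:
            hit = extract_barcode(sequence, qualities, spec, read_id=read_id)
        except MalformedReadError as exc:
            raise MalformedReadError(f"record {idx} ({read_id!r}): {exc}") from exc
        if hit is not None:
            counts[hit.sequence] += 1
    usable = sum(counts.values())
    return BarcodeCounts(counts=dict(counts), total_reads=total, usable_reads=usable)


def hamming1_neighbors(barcode: str) -> Iterator[str]:
    """All sequences at Hamming distance exactly 1 from ``barcode``."""
    for i, original in enumerate(barcode):
        for base in _BASES:
            if base != original:
                yield barcode[:i] + base + barcode[i + 1 :]


def filter_one_off_barcodes(counts: BarcodeCounts) -> BarcodeCounts:
    """Drop barcodes that look like single-substitution errors of a real one.

    Two barcodes are *similar* when they differ at exactly one position.  A
    barcode is kept iff it has no similar barcode in the table, or its count
    is at least twice the count of its most abundant similar barcode
    (inclusive: ``count >= 2 * max_neighbor``).  Every barcode is judged
    against the original, unfiltered table, so the outcome does not depend on
    processing order.
    """
    table: Mapping[str, int] = counts.counts
    kept: dict[str, int] = {}
    for barcode, count in table.items():
        max_neighbor = 0
        for neighbor in hamming1_neighbors(barcode):
            c = table.get(neighbor, 0)
            if c > max_neighbor:
                max_neighbor = c
        if max_neighbor == 0 or count >= 2 * max_neighbor:
            kept[barcode] = count
    return BarcodeCounts(
        counts=kept,
        total_reads=counts.total_reads,
        usable_reads=sum(kept.values()),
    )
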