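"""Building the barcoded-fragment reference set.

Three stages, each mirroring one sequencing assay of the library:

1. Barcode-pair association: reads carrying both the UP and the DOWN barcode
   of one plasmid are parsed with two anchor specs; one-mismatch artifact
   barcodes and chimeric-PCR pairs are filtered out
   (:func:`associate_barcode_pairs`, :func:`filter_chimeric_pairs`).
2. Barcode-to-genome mapping: the genomic tail downstream of each barcode is
   aligned to the reference genome by exact 15-mer seeding with ungapped
   extension and a single-indel rescue; reads mapping to more than one
   location (repeats) are ignored, and each barcode keeps its dominant
   location only if that location is at least twice as frequent as any other
   (:func:`map_tail_to_genome`, :func:`resolve_barcode_locations`).
3. The join: barcode pairs whose two junctions lie on the same contig, face
   each other, and span 100-6000 nt become reference fragments
   (:func:`build_reference_set`).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .barcodes import (
    BarcodeCounts,
    FlankSpec,
    extract_barcode,
    filter_one_off_barcodes,
)

__all__ = [
    "BarcodePair",
    "BarcodeMapping",
    "ReferenceFragment",
    "AlignmentHit",
    "GenomeIndex",
    "PairAssociationResult",
    "associate_barcode_pairs",
    "filter_chimeric_pairs",
    "map_tail_to_genome",
    "mapping_from_hit",
    "resolve_barcode_locations",
    "build_reference_set",
    "read_psl_hits",
    "revcomp",
]

MIN_FRAGMENT_LENGTH = 100
MAX_FRAGMENT_LENGTH = 6000
MIN_BLOCK_SIZE = 15
MAX_INDELS = 1

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class BarcodePair:
    """An UP/DOWN barcode pair observed on the same plasmid."""

    up: str
    down: str
    read_count: int

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class BarcodeMapping:
    """A barcode's resolved genomic junction.

    ``junction`` is the first genomic base of the cloned insert adjacent to
    this barcode's anchor (0-based).  ``direction`` is '+' when the insert
    extends toward higher coordinates from the junction, '-' toward lower.
    """

    barcode: str
    contig: str
    junction: int
    direction: str
    read_count: int

    def __post_init__(self) -> None:
        if self.direction not in "+-":
            raise ValueError("direction must be '+' or '-'")
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


@dataclass(frozen=True)
class ReferenceFragment:
    """A barcoded genomic fragment: UP+DOWN barcodes bound to an interval."""

    up: str
    down: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentHit:
    """A qualifying alignment of a genomic tail."""

    contig: str
    position: int
    strand: str
    block_size: int
    indels: int
    matches: int = 0


@dataclass
class PairAssociationResult:
    pairs: list[BarcodePair]
    total_reads: int = 0
    usable_reads: int = 0
    dropped_one_off: int = 0


# ---------------------------------------------------------------------------
# Barcode pair association (BPseq)
# ---------------------------------------------------------------------------

def associate_barcode_pairs(
    reads: Iterable[Tuple[str, str, Sequence[int]]],
    up_spec: FlankSpec,
    down_spec: FlankSpec,
) -> PairAssociationResult:
    """Extract UP and DOWN barcodes from each read and tally pairs.

    Reads where only one barcode extracts are counted as unusable, not
    errors.  After tallying, the one-off (Hamming-1, 2x) filter is applied to
    the UP and DOWN barcode tables independently; any pair containing a
    removed barcode is dropped.
    """
    pair_counts: Counter[Tuple[str, str]] = Counter()
    total = 0
    for read_id, seq, quals in reads:
        total += 1
        up = extract_barcode(seq, quals, up_spec, read_id=read_id)
        down = extract_barcode(seq, quals, down_spec, read_id=read_id)
        if up is not None and down is not None:
            pair_counts[(up.sequence, down.sequence)] += 1
    usable = sum(pair_counts.values())

    up_counts: Counter[str] = Counter()
    down_counts: Counter[str] = Counter()
    for (up_bc, down_bc), c in pair_counts.items():
        up_counts[up_bc] += c
        down_counts[down_bc] += c
    up_kept = set(
        filter_one_off_barcodes(
            BarcodeCounts(dict(up_counts), usable, usable)
        ).counts
    )
    down_kept = set(
        filter_one_off_barcodes(
            BarcodeCounts(dict(down_counts), usable, usable)
        ).counts
    )

    pairs = []
    dropped = 0
    for (up_bc, down_bc), c in sorted(pair_counts.items()):
        if up_bc in up_kept and down_bc in down_kept:
            pairs.append(BarcodePair(up_bc, down_bc, c))
        else:
            dropped += 1
    return PairAssociationResult(
        pairs=pairs, total_reads=total, usable_reads=usable, dropped_one_off=dropped
    )


def filter_chimeric_pairs(pairs: Sequence[BarcodePair]) -> list[BarcodePair]:
    """Remove likely chimeric-PCR barcode pairs.

    Two pairs are *related* when they share the UP or the DOWN barcode.  A
    pair is kept iff it has no related pair, or its read count is at least
    twice the count of its most abundant related pair.  All pairs are judged
    against the unfiltered table.
    """
    by_up: dict[str, list[int]] = defaultdict(list)
    by_down: dict[str, list[int]] = defaultdict(list)
    for i, p in enumerate(pairs):
        by_up[p.up].append(i)
        by_down[p.down].append(i)

    def max_related(i: int) -> int:
        p = pairs[i]
        best = 0
        for j in by_up[p.up]:
            if j != i and pairs[j].read_count > best:
                best = pairs[j].read_count
        for j in by_down[p.down]:
            if j != i and pairs[j].read_count > best:
                best = pairs[j].read_count
        return best

    kept = []
    for i, p in enumerate(pairs):
        rival = max_related(i)
        if rival == 0 or p.read_count >= 2 * rival:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Tail-to-genome mapping (BAGseq)
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Exact k-mer index over a genome for seed-and-extend tail mapping."""

    def __init__(self, contigs: Mapping[str, str], k: int = MIN_BLOCK_SIZE):
        self.k = k
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self._index: dict[str, list[Tuple[str, int]]] = defaultdict(list)
        for name, seq in self.contigs.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))

    def seed_positions(self, kmer: str) -> list[Tuple[str, int]]:
        return self._index.get(kmer, [])


def _match_stats(a: str, b: str) -> Tuple[int, int]:
    """(longest exact run, total matches) of two equal-length strings."""
    best = run = total = 0
    for x, y in zip(a, b):
        if x == y:
            run += 1
            total += 1
            if run > best:
                best = run
        else:
            run = 0
    return best, total


def _evaluate_candidate(
    query: str, target: str, start: int
) -> Tuple[int, int, int]:
    """Best (block, indels, matches) of aligning ``query`` at ``target[start:]``
    allowing at most one indel."""
    n = len(query)

    def segment(s: int, length: int) -> str:
        if s < 0:
            return "N" * min(length, -s) + target[0 : max(0, s + length)]
        seg = target[s : s + length]
        return seg + "N" * (length - len(seg))

    block, matches = _match_stats(query, segment(start, n))
    best = (block, 0, matches)
    for split in range(1, n):
        pre_block, pre_match = _match_stats(query[:split], segment(start, split))
        for shift in (-1, 1):
            suf_block, suf_match = _match_stats(
                query[split:], segment(start + split + shift, n - split)
            )
            cand = (max(pre_block, suf_block), 1, pre_match + suf_match)
            # prefer more matches; among equals, fewer indels
            if (cand[2], -cand[1]) > (best[2], -best[1]):
                best = cand
    return best


def map_tail_to_genome(
    tail: str,
    index: GenomeIndex,
    min_block: int = MIN_BLOCK_SIZE,
    max_indels: int = MAX_INDELS,
    min_identity: float = 0.9,
) -> Optional[AlignmentHit]:
    """Map a genomic tail to its unique location, or ``None``.

    Seeds every exact ``k``-mer of the tail (both strands) against the genome
    index, extends each candidate diagonal without gaps and rescues at most
    one indel.  A candidate qualifies when its longest exact block is at
    least ``min_block`` nt, it has at most ``max_indels`` indels and at least
    ``min_identity`` of its bases match.  Tails with zero or more than one
    qualifying location (repeats) return ``None``.
    """
    tail = tail.upper()
    k = index.k
    if len(tail) < k:
        return None
    hits: list[AlignmentHit] = []
    seen: set[Tuple[str, str, int]] = set()
    for strand, query in (("+", tail), ("-", revcomp(tail))):
        candidates: set[Tuple[str, int]] = set()
        for off in range(len(query) - k + 1):
            for contig, pos in index.seed_positions(query[off : off + k]):
                candidates.add((contig, pos - off))
        for contig, start in candidates:
            key = (strand, contig, start)
            if key in seen:
                continue
            seen.add(key)
            block, indels, matches = _evaluate_candidate(
                query, index.contigs[contig], start
            )
            if (
                block >= min_block
                and indels <= max_indels
                and matches >= min_identity * len(query)
            ):
                hits.append(
                    AlignmentHit(contig, start, strand, block, indels, matches)
                )
    return _unique_hit(hits)


def _unique_hit(hits: list[AlignmentHit], wobble: int = 10) -> Optional[AlignmentHit]:
    """Collapse near-duplicate hits (indel off-by-ones); require one location."""
    if not hits:
        return None
    clusters: list[list[AlignmentHit]] = []
    for hit in sorted(hits, key=lambda h: (h.contig, h.strand, h.position)):
        placed = False
        for cluster in clusters:
            ref = cluster[0]
            if (
                ref.contig == hit.contig
                and ref.strand == hit.strand
                and abs(ref.position - hit.position) <= wobble
            ):
                cluster.append(hit)
                placed = True
                break
        if not placed:
            clusters.append([hit])
    if len(clusters) != 1:
        return None
    return max(clusters[0], key=lambda h: (h.matches, -h.indels))


def read_psl_hits(path) -> dict[str, list[AlignmentHit]]:
    """Import pre-computed alignments in PSL format (e.g. from BLAT).

    Hits are converted to :class:`AlignmentHit` records; the same acceptance
    rules (block size, indels, uniqueness) are applied downstream via
    :func:`psl_best_hit`.
    """
    hits: dict[str, list[AlignmentHit]] = defaultdict(list)
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 21 or not parts[0].isdigit():
                continue  # header lines
            matches = int(parts[0])
            q_inserts, t_inserts = int(parts[4]), int(parts[6])
            strand = parts[8]
            qname = parts[9]
            tname = parts[13]
            tstart = int(parts[15])
            block_sizes = [int(b) for b in parts[18].rstrip(",").split(",")]
            hits[qname].append(
                AlignmentHit(
                    contig=tname,
                    position=tstart,
                    strand=strand,
                    block_size=max(block_sizes),
                    indels=q_inserts + t_inserts,
                    matches=matches,
                )
            )
    return dict(hits)


def psl_best_hit(
    hits: Sequence[AlignmentHit],
    min_block: int = MIN_BLOCK_SIZE,
    max_indels: int = MAX_INDELS,
) -> Optional[AlignmentHit]:
    """Apply block/indel/uniqueness acceptance to imported hits."""
    qualifying = [
        h for h in hits if h.block_size >= min_block and h.indels <= max_indels
    ]
    return _unique_hit(qualifying)


def mapping_from_hit(
    barcode: str, hit: AlignmentHit, tail_length: int, read_count: int = 1
) -> BarcodeMapping:
    """Convert a tail alignment into a barcode junction.

    The tail starts at the insert breakpoint next to the barcode.  A
    plus-strand hit means the insert extends rightward from the alignment
    start; a minus-strand hit means the breakpoint is at the alignment's
    right edge and the insert extends leftward.
    """
    if hit.strand == "+":
        return BarcodeMapping(barcode, hit.contig, hit.position, "+", read_count)
    return BarcodeMapping(
        barcode, hit.contig, hit.position + tail_length, "-", read_count
    )


def resolve_barcode_locations(
    tallies: Mapping[str, Mapping[Tuple[str, int, str], int]],
) -> list[BarcodeMapping]:
    """Resolve each barcode to a single dominant junction.

    ``tallies`` maps barcode -> {(contig, junction, direction): read_count}.
    A barcode is kept with its top location iff it has a single location or
    the top location's count is at least twice every other location's count;
    otherwise it is discarded (ambiguous: chimeric or multiply cloned).
    """
    mappings = []
    for barcode in sorted(tallies):
        locs = tallies[barcode]
        ranked = sorted(locs.items(), key=lambda kv: -kv[1])
        (contig, junction, direction), top_count = ranked[0]
        if len(ranked) > 1 and top_count < 2 * ranked[1][1]:
            continue
        mappings.append(
            BarcodeMapping(barcode, contig, junction, direction, top_count)
        )
    return mappings


# ---------------------------------------------------------------------------
# The join (reference set)
# ---------------------------------------------------------------------------

def build_reference_set(
    pairs: Sequence[BarcodePair],
    up_maps: Sequence[BarcodeMapping],
    down_maps: Sequence[BarcodeMapping],
    min_length: int = MIN_FRAGMENT_LENGTH,
    max_length: int = MAX_FRAGMENT_LENGTH,
) -> Tuple[list[ReferenceFragment], Counter]:
    """Join barcode pairs with their junction mappings into fragments.

    For each pair whose UP and DOWN barcodes both resolved: require the same
    contig, inward-facing junctions (the lower junction extends '+', the
    higher '-') and a spanned length within ``[min_length, max_length]``.
    Fragments sharing a barcode with an earlier fragment are dropped so every
    barcode belongs to exactly one fragment.  Returns the fragments and a
    counter of drop reasons.
    """
    up_by_bc = {m.barcode: m for m in up_maps}
    down_by_bc = {m.barcode: m for m in down_maps}
    dropped: Counter = Counter()
    fragments: list[ReferenceFragment] = []
    used_up: set[str] = set()
    used_down: set[str] = set()
    for pair in pairs:
        um = up_by_bc.get(pair.up)
        dm = down_by_bc.get(pair.down)
        if um is None or dm is None:
            dropped["unmapped_barcode"] += 1
            continue
        if um.contig != dm.contig:
            dropped["different_contigs"] += 1
            continue
        lo, hi = sorted([(um.junction, um.direction), (dm.junction, dm.direction)])
        if lo[0] == hi[0]:
            dropped["zero_length"] += 1
            continue
        if not (lo[1] == "+" and hi[1] == "-"):
            dropped["not_inward_facing"] += 1
            continue
        length = hi[0] - lo[0]
        if not (min_length <= length <= max_length):
            dropped["length_out_of_range"] += 1
            continue
        if pair.up in used_up or pair.down in used_down:
            dropped["duplicate_barcode"] += 1
            continue
        used_up.add(pair.up)
        used_down.add(pair.down)
        fragments.append(
            ReferenceFragment(pair.up, pair.down, um.contig, lo[0], hi[0])
        )
    return fragments, dropped
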