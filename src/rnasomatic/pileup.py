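"""Read-level QC and spliced pileup construction.

RNA-seq reads are aligned across introns, so a read contributes evidence only
at positions inside its aligned (M/X/=) blocks; positions spanned by an
N-CIGAR gap are spliced out and carry no evidence.  Each retained base is
annotated with the distances the downstream artifact filters need: distance
to the nearer aligned read end and distance to the nearest splice junction
within the read.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pysam

INF = float("inf")


@dataclass(slots=True)
class ReadRecord:
    """One QC-passed spliced alignment.

    ``aligned_blocks`` are the genomic (start, end) intervals, 1-based
    inclusive, obtained by splitting the alignment at N-CIGAR junctions;
    they are sorted and non-overlapping.  ``bases``/``qualities`` cover the
    aligned bases only, concatenated across blocks in genomic order.
    """

    read_id: str
    pair_id: str
    chrom: str
    aligned_blocks: list[tuple[int, int]]
    strand: str
    mapping_quality: int
    is_proper_pair: bool
    is_primary: bool
    is_duplicate: bool
    bases: str
    qualities: Sequence[int]

    @property
    def start(self) -> int:
        return self.aligned_blocks[0][0]

    @property
    def end(self) -> int:
        return self.aligned_blocks[-1][1]


class Observation:
    """One read's evidence at one genomic position."""

    __slots__ = (
        "base",
        "qual",
        "strand",
        "mapq",
        "dist_to_read_end",
        "dist_to_junction",
        "read_id",
        "pair_id",
        "realignment_confirmed",
        "not_near_end_or_junction",
    )

    def __init__(
        self,
        base: str,
        qual: int,
        strand: str,
        mapq: int,
        dist_to_read_end: int,
        dist_to_junction: float,
        read_id: str,
        pair_id: str,
    ) -> None:
        self.base = base
        self.qual = qual
        self.strand = strand
        self.mapq = mapq
        self.dist_to_read_end = dist_to_read_end
        self.dist_to_junction = dist_to_junction
        self.read_id = read_id
        self.pair_id = pair_id
        self.realignment_confirmed: bool | None = None
        self.not_near_end_or_junction: bool | None = None

    @property
    def error_prob(self) -> float:
        return 10.0 ** (-self.qual / 10.0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Observation({self.base}, q={self.qual}, {self.strand}, "
            f"end={self.dist_to_read_end}, junc={self.dist_to_junction})"
        )


@dataclass(slots=True)
class PileupSite:
    """All (mate-deduplicated) observations at one position."""

    chrom: str
    pos: int
    ref_base: str
    observations: list[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)

    def base_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for obs in self.observations:
            counts[obs.base] = counts.get(obs.base, 0) + 1
        return counts


@dataclass(slots=True)
class QcConfig:
    """Read-level inclusion gates.

    ``min_mapq`` operationalises removal of ambiguous alignments; STAR
    assigns MAPQ 255 to unique mappers, so the default of 20 passes them
    while dropping multi-mappers.
    """

    min_mapq: int = 20
    require_proper_pair: bool = True
    single_end: bool = False


def _aligned_blocks_from_cigar(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic blocks (1-based inclusive) split at N operations."""
    blocks: list[tuple[int, int]] = []
    pos = aln.reference_start + 1  # to 1-based
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            if blocks and blocks[-1][1] == pos - 1:
                # merge contiguous matched segments (e.g. M X M)
                blocks[-1] = (blocks[-1][0], pos + length - 1)
            else:
                blocks.append((pos, pos + length - 1))
            pos += length
        elif op in (2, 3):  # D, N consume reference
            pos += length
        # I, S, H, P consume no reference
    return blocks


def _aligned_query(aln: pysam.AlignedSegment) -> tuple[str, list[int]]:
    """Query bases/qualities at aligned (reference-consuming M/=/X) positions."""
    seq = aln.query_sequence or ""
    quals = aln.query_qualities
    bases: list[str] = []
    qs: list[int] = []
    qpos = 0
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):
            bases.append(seq[qpos : qpos + length])
            qs.extend(quals[qpos : qpos + length])
            qpos += length
        elif op in (1, 4):  # I, S consume query only
            qpos += length
    return "".join(bases), qs


def read_passes_qc(aln: pysam.AlignedSegment, qc: QcConfig) -> bool:
    if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
        return False
    if aln.is_duplicate:
        return False
    if qc.require_proper_pair and not qc.single_end and not aln.is_proper_pair:
        return False
    if aln.mapping_quality < qc.min_mapq:
        return False
    return True


def record_from_alignment(aln: pysam.AlignedSegment) -> ReadRecord:
    mate = "/2" if aln.is_read2 else "/1"
    bases, quals = _aligned_query(aln)
    return ReadRecord(
        read_id=aln.query_name + mate,
        pair_id=aln.query_name,
        chrom=aln.reference_name,
        aligned_blocks=_aligned_blocks_from_cigar(aln),
        strand="-" if aln.is_reverse else "+",
        mapping_quality=aln.mapping_quality,
        is_proper_pair=aln.is_proper_pair,
        is_primary=not (aln.is_secondary or aln.is_supplementary),
        is_duplicate=aln.is_duplicate,
        bases=bases,
        qualities=quals,
    )


def load_reads(
    alignment_path: str,
    region: str | None = None,
    qc_config: QcConfig | None = None,
) -> Iterator[ReadRecord]:
    """Stream QC-passed reads from a coordinate-sorted SAM/BAM file.

    With ``region`` of the form ``chrom`` or ``chrom:start-end``, a BAM index
    is required for random access unless the file is SAM text, in which case
    the stream is filtered during a full scan.  Raises ``FileNotFoundError``
    if a BAM region query has no index.
    """
    qc = qc_config or QcConfig()
    mode = "r" if alignment_path.endswith(".sam") else "rb"
    with pysam.AlignmentFile(alignment_path, mode) as handle:
        if region is not None and mode == "rb":
            if not handle.has_index():
                raise FileNotFoundError(
                    f"region query on {alignment_path} requires a BAM index"
                )
            chrom = region.split(":")[0]
            if chrom not in handle.references:
                return
            iterator = handle.fetch(region=region)
        else:
            iterator = handle
        chrom_filter: str | None = None
        span: tuple[int, int] | None = None
        if region is not None and mode == "r":
            chrom_filter, _, rest = region.partition(":")
            if rest:
                lo, _, hi = rest.partition("-")
                span = (int(lo), int(hi))
        for aln in iterator:
            if aln.is_unmapped:
                continue
            if chrom_filter is not None and aln.reference_name != chrom_filter:
                continue
            if span is not None and (
                aln.reference_start + 1 > span[1] or aln.reference_end < span[0]
            ):
                continue
            if read_passes_qc(aln, qc):
                yield record_from_alignment(aln)


def observations_of(read: ReadRecord) -> Iterator[tuple[int, Observation]]:
    """Yield (position, Observation) for every aligned base of the read.

    ``dist_to_read_end`` is the distance (bp) to the nearer end of the
    aligned read, counted along the read (junction gaps excluded);
    ``dist_to_junction`` is the distance to the nearest N junction within
    the read, or infinity for an unspliced read.
    """
    total = len(read.bases)
    junctions = len(read.aligned_blocks) > 1
    offset = 0
    blocks = read.aligned_blocks
    nblocks = len(blocks)
    for bi, (bstart, bend) in enumerate(blocks):
        blen = bend - bstart + 1
        for i in range(blen):
            pos = bstart + i
            read_off = offset + i
            dist_end = min(read_off, total - 1 - read_off)
            if junctions:
                left = INF if bi == 0 else i
                right = INF if bi == nblocks - 1 else blen - 1 - i
                dist_junc: float = min(left, right)
            else:
                dist_junc = INF
            yield pos, Observation(
                base=read.bases[read_off],
                qual=int(read.qualities[read_off]),
                strand=read.strand,
                mapq=read.mapping_quality,
                dist_to_read_end=dist_end,
                dist_to_junction=dist_junc,
                read_id=read.read_id,
                pair_id=read.pair_id,
            )
        offset += blen


class ReferenceLookup:
    """Minimal protocol: ``fetch_base(chrom, pos)`` with pos 1-based."""

    def __init__(self, fasta) -> None:  # pyfaidx.Fasta or dict of str
        self._fasta = fasta

    def fetch_base(self, chrom: str, pos: int) -> str:
        seq = self._fasta[chrom]
        if isinstance(seq, str):
            return seq[pos - 1].upper()
        return str(seq[pos - 1 : pos]).upper()

    def __contains__(self, chrom: str) -> bool:
        if isinstance(self._fasta, dict):
            return chrom in self._fasta
        return chrom in self._fasta.keys()


def build_pileups(
    reads: Iterable[ReadRecord],
    reference: ReferenceLookup,
    min_depth: int = 10,
    count_n_in_depth: bool = False,
) -> Iterator[PileupSite]:
    """Sweep coordinate-sorted reads into per-position pileups.

    Sites are emitted in strictly increasing (chrom, pos) order, with depth
    counted after two hygiene steps: overlapping mates of one pair
    contribute their higher-quality base once, and N base calls are dropped
    unless ``count_n_in_depth``.  Only sites with resulting depth >=
    ``min_depth`` are emitted.
    """
    pending: dict[int, dict[str, Observation]] = {}
    current_chrom: str | None = None
    last_start = 0

    def flush(upto: int | None) -> Iterator[PileupSite]:
        if not pending:
            return
        ready = sorted(p for p in pending if upto is None or p < upto)
        for pos in ready:
            per_pair = pending.pop(pos)
            obs = list(per_pair.values())
            if not count_n_in_depth:
                obs = [o for o in obs if o.base != "N"]
            if len(obs) >= min_depth:
                yield PileupSite(
                    chrom=current_chrom,
                    pos=pos,
                    ref_base=reference.fetch_base(current_chrom, pos),
                    observations=obs,
                )

    for read in reads:
        if read.chrom != current_chrom:
            if current_chrom is not None and read.chrom not in reference:
                raise ValueError(
                    f"contig {read.chrom!r} present in alignments but absent "
                    "from the reference FASTA"
                )
            yield from flush(None)
            current_chrom = read.chrom
            if current_chrom not in reference:
                raise ValueError(
                    f"contig {current_chrom!r} present in alignments but absent "
                    "from the reference FASTA"
                )
            last_start = 0
        if read.start < last_start:
            raise ValueError("alignment file is not coordinate-sorted")
        last_start = read.start
        yield from flush(read.start)
        for pos, ob in observations_of(read):
            slot = pending.setdefault(pos, {})
            prev = slot.get(ob.pair_id)
            if prev is None or ob.qual > prev.qual:
                slot[ob.pair_id] = ob
    yield from flush(None)


def annotate_read_end_flags(
    site: PileupSite, near_end_bp: int = 6, near_junction_bp: int = 5
) -> PileupSite:
    """Set ``not_near_end_or_junction`` on every observation in place.

    True only when the base sits at least ``near_end_bp`` from both aligned
    read ends and at least ``near_junction_bp`` from any splice junction.
    """
    for obs in site.observations:
        obs.not_near_end_or_junction = (
            obs.dist_to_read_end >= near_end_bp
            and obs.dist_to_junction >= near_junction_bp
        )
    return site
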