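"""Seeded synthetic data: reference, gene models, planted truth, reads.

The generator emulates a stranded paired-end mRNA-seq experiment over a
random genome with multi-exon genes on alternating strands.  Planted truth
classes and the filter each is expected to exercise:

mosaic               clonal somatic variants at specified fractions (kept)
germline_het         VAF-0.5 heterozygotes, also written to a population VCF
editing              A>G on + genes / T>C on - genes (strand rule, editing DB)
oxo_g_artifact       G>T on + genes / C>A on - genes, alternate allele only
                     on forward-orientation reads (strand-bias test, or the
                     oxidation rule set when enabled)
strand_bias_artifact any substitution with forward-only alternate support
misalignment_cluster three linked substitutions carried by one read subset
                     (complete-linkage filter)

Fragments are sampled uniformly over each transcript interior; every read
covering a planted site carries the alternate with probability equal to the
record's expected VAF (one draw per fragment, shared across a cluster's
sites).  Base qualities are constant, q = -10 log10(base_error), so the
genotyper's error model matches the simulation exactly.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pysam

from .editing import GeneModel
from .filters import homopolymer_scan

_BASES = np.array(list("ACGT"))
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# substitutions that would collide with an editing or oxidation strand
# signature, per gene strand; mosaic plants avoid these
_SIGNATURE_SUBS = {
    "+": {("A", "G"), ("G", "T")},
    "-": {("T", "C"), ("C", "A")},
}


@dataclass(slots=True)
class TruthRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    class_label: str
    expected_vaf: float
    gene_id: str | None = None
    cluster_id: str | None = None

    @property
    def strand_restricted(self) -> bool:
        """Alternate allele appears only on forward-orientation reads."""
        return self.class_label in ("oxo_g_artifact", "strand_bias_artifact")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MixtureDesign:
    """Cell-line mixture: line proportions and per-line variant copies."""

    lines: list[tuple[str, float]]
    genotypes: dict = field(default_factory=dict)  # (line_id, variant_key) -> 0/1/2

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.lines)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")

    def expected_vaf(self, variant_key) -> float:
        return sum(
            prop * self.genotypes.get((line_id, variant_key), 0) / 2.0
            for line_id, prop in self.lines
        )


@dataclass
class SyntheticGenome:
    chrom: str
    sequence: str
    genes: list[GeneModel]
    duplicated_gene_id: str | None = None

    def transcript_positions(self, gene: GeneModel) -> list[int]:
        """Genomic positions (1-based) in transcript 5'->3' order."""
        pos = [p for s, e in gene.exons for p in range(s, e + 1)]
        return pos if gene.strand == "+" else pos[::-1]


def generate_reference_and_genes(
    seed: int,
    n_genes: int = 40,
    gene_length: int = 3000,
    gc: float = 0.5,
    chrom: str = "chr1",
    chrom_length: int | None = None,
    exons_per_gene: tuple[int, int] = (4, 6),
    exon_length: tuple[int, int] = (160, 240),
    intron_length: tuple[int, int] = (60, 400),
    duplicate_segment: bool = True,
    homopolymer_runs: int = 2,
) -> SyntheticGenome:
    """Deterministic random genome with alternating-strand multi-exon genes.

    Genes are laid out left to right with strands +,-,+,-,...; introns are
    at least 60 bp.  Optionally a 200 bp piece of the first gene is copied
    into intergenic space (a tandem-like duplication that defeats unique
    realignment) and a couple of long homopolymer runs are planted in
    intergenic space for the region-mask filter.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    layouts: list[list[tuple[int, int]]] = []
    spans: list[int] = []
    for gi in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        ex_lens = rng.integers(exon_length[0], exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(intron_length[0], intron_length[1] + 1, size=n_ex - 1)
        rel = []
        cursor = 0
        for i, el in enumerate(ex_lens):
            rel.append((cursor, cursor + int(el) - 1))
            cursor += int(el)
            if i < n_ex - 1:
                cursor += int(in_lens[i])
        layouts.append(rel)
        spans.append(cursor)
    total_span = sum(spans)
    if chrom_length is None:
        gap = 500
        chrom_length = total_span + gap * (n_genes + 1)
    slack = chrom_length - total_span
    if slack < 100 * (n_genes + 1):
        raise ValueError("chrom_length too small for the requested genes")
    gap = slack // (n_genes + 1)
    cursor = gap
    for gi, rel in enumerate(layouts):
        exons = [(cursor + s + 1, cursor + e + 1) for s, e in rel]  # to 1-based
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:03d}",
                chrom=chrom,
                strand="+" if gi % 2 == 0 else "-",
                exons=exons,
            )
        )
        cursor += spans[gi] + gap

    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=chrom_length, p=p)

    dup_gene = None
    if duplicate_segment and genes:
        dup_gene = genes[0].gene_id
        src_exon = genes[0].exons[len(genes[0].exons) // 2]
        s = src_exon[0] - 1
        length = min(200, src_exon[1] - src_exon[0] + 1)
        dest = chrom_length - length - 50
        seq[dest : dest + length] = seq[s : s + length]

    for _ in range(homopolymer_runs):
        pos = int(rng.integers(0, max(1, gap - 20)))
        base = str(rng.choice(_BASES))
        seq[pos : pos + 8] = base

    return SyntheticGenome(
        chrom=chrom,
        sequence="".join(seq),
        genes=genes,
        duplicated_gene_id=dup_gene,
    )


def write_fasta(genome: SyntheticGenome, path: str) -> None:
    with open(path, "w") as handle:
        handle.write(f">{genome.chrom}\n")
        handle.write(textwrap.fill(genome.sequence, 60) + "\n")


def write_gtf(genome: SyntheticGenome, path: str) -> None:
    with open(path, "w") as handle:
        for gene in genome.genes:
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
            handle.write(
                "\t".join(
                    [
                        genome.chrom,
                        "rnasomatic_sim",
                        "gene",
                        str(gene.start),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in gene.exons:
                handle.write(
                    "\t".join(
                        [
                            genome.chrom,
                            "rnasomatic_sim",
                            "exon",
                            str(s),
                            str(e),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


@dataclass
class TruthDesign:
    """Counts and allele-fraction ranges for each planted class."""

    n_mosaic: int = 30
    mosaic_vaf: tuple[float, float] = (0.10, 0.40)
    n_germline_het: int = 30
    n_editing: int = 60
    editing_vaf: tuple[float, float] = (0.15, 0.60)
    n_oxog: int = 12
    oxog_vaf: tuple[float, float] = (0.25, 0.40)
    n_strand_bias: int = 12
    strand_bias_vaf: tuple[float, float] = (0.25, 0.40)
    n_misalignment_clusters: int = 5
    cluster_vaf: tuple[float, float] = (0.20, 0.35)
    cluster_span: int = 60
    min_spacing: int = 15
    interior_margin: int = 260  # transcript bp kept clear of transcript ends
    junction_margin: int = 8  # genomic bp kept clear of exon boundaries
    mixture: MixtureDesign | None = None


def _interior_positions(
    genome: SyntheticGenome, gene: GeneModel, design: TruthDesign
) -> list[int]:
    """Genomic positions eligible for planting within one gene."""
    tpos = genome.transcript_positions(gene)
    lo, hi = design.interior_margin, len(tpos) - design.interior_margin
    if hi <= lo:
        return []
    eligible = []
    for p in tpos[lo:hi]:
        near_junction = any(
            abs(p - edge) < design.junction_margin
            for s, e in gene.exons
            for edge in (s, e)
        )
        if not near_junction:
            eligible.append(p)
    return sorted(eligible)


def plant_truth(
    seed: int, genome: SyntheticGenome, design: TruthDesign | None = None
) -> list[TruthRecord]:
    """Plant every truth class at unique, well-separated exonic positions.

    Sites fall in transcript interiors (uniform coverage under the read
    simulator), away from exon boundaries and homopolymer runs, and never
    in the gene carrying the duplicated segment.  Mosaic substitutions
    avoid the editing/oxidation strand signatures of their host gene so a
    perfectly specific editing filter costs no mosaic sensitivity.
    """
    design = design or TruthDesign()
    rng = np.random.default_rng(seed)
    hp_mask = homopolymer_scan({genome.chrom: genome.sequence})
    usable_genes = [
        g for g in genome.genes if g.gene_id != genome.duplicated_gene_id
    ]
    pool: list[tuple[GeneModel, int]] = []
    for gene in usable_genes:
        for p in _interior_positions(genome, gene, design):
            if not hp_mask.contains(genome.chrom, p):
                pool.append((gene, p))
    rng.shuffle(pool)
    taken: list[int] = []
    records: list[TruthRecord] = []

    def far_enough(pos: int, spacing: int) -> bool:
        return all(abs(pos - t) >= spacing for t in taken)

    def draw(want_ref: str | None, gene_strand: str | None = None):
        for idx in range(len(pool)):
            gene, pos = pool[idx]
            if gene_strand is not None and gene.strand != gene_strand:
                continue
            if want_ref is not None and genome.sequence[pos - 1] != want_ref:
                continue
            if not far_enough(pos, design.min_spacing):
                continue
            pool.pop(idx)
            taken.append(pos)
            return gene, pos
        raise RuntimeError("ran out of eligible planting positions")

    def other_base(ref: str, exclude: set) -> str:
        choices = [b for b in "ACGT" if b != ref and (ref, b) not in exclude]
        return str(choices[int(rng.integers(len(choices)))])

    def uniform(lohi: tuple[float, float]) -> float:
        return float(np.round(rng.uniform(*lohi), 4))

    for i in range(design.n_mosaic):
        gene, pos = draw(None)
        ref = genome.sequence[pos - 1]
        alt = other_base(ref, _SIGNATURE_SUBS[gene.strand])
        records.append(
            TruthRecord(genome.chrom, pos, ref, alt, "mosaic", uniform(design.mosaic_vaf), gene.gene_id)
        )

    for i in range(design.n_germline_het):
        gene, pos = draw(None)
        ref = genome.sequence[pos - 1]
        alt = other_base(ref, _SIGNATURE_SUBS[gene.strand])
        key = (genome.chrom, pos, ref, alt)
        vaf = 0.5 if design.mixture is None else design.mixture.expected_vaf(key)
        records.append(
            TruthRecord(genome.chrom, pos, ref, alt, "germline_het", vaf, gene.gene_id)
        )

    for i in range(design.n_editing):
        strand = "+" if i % 2 == 0 else "-"
        ref, alt = ("A", "G") if strand == "+" else ("T", "C")
        gene, pos = draw(ref, strand)
        records.append(
            TruthRecord(genome.chrom, pos, ref, alt, "editing", uniform(design.editing_vaf), gene.gene_id)
        )

    for i in range(design.n_oxog):
        strand = "+" if i % 2 == 0 else "-"
        ref, alt = ("G", "T") if strand == "+" else ("C", "A")
        gene, pos = draw(ref, strand)
        records.append(
            TruthRecord(genome.chrom, pos, ref, alt, "oxo_g_artifact", uniform(design.oxog_vaf), gene.gene_id)
        )

    sb_exclude = {("A", "G"), ("T", "C"), ("G", "T"), ("C", "A")}
    for i in range(design.n_strand_bias):
        gene, pos = draw(None)
        ref = genome.sequence[pos - 1]
        alt = other_base(ref, sb_exclude)
        records.append(
            TruthRecord(
                genome.chrom, pos, ref, alt, "strand_bias_artifact",
                uniform(design.strand_bias_vaf), gene.gene_id,
            )
        )

    for ci in range(design.n_misalignment_clusters):
        vaf = uniform(design.cluster_vaf)
        cluster_id = f"cluster{ci + 1}"
        # three linked sites within one exon, sharing covering fragments
        for attempt in range(200):
            gene, anchor = draw(None)
            exon = next((s, e) for s, e in gene.exons if s <= anchor <= e)
            offsets = [0, design.cluster_span // 2, design.cluster_span]
            sites = [anchor + off for off in offsets]
            if all(
                exon[0] <= sp <= exon[1]
                and not hp_mask.contains(genome.chrom, sp)
                and (sp == anchor or far_enough(sp, 5))
                for sp in sites
            ):
                break
        else:  # pragma: no cover - pool exhaustion
            raise RuntimeError("could not place misalignment cluster")
        for sp in sites:
            if sp != anchor:
                taken.append(sp)
            ref = genome.sequence[sp - 1]
            alt = other_base(ref, _SIGNATURE_SUBS[gene.strand])
            records.append(
                TruthRecord(
                    genome.chrom, sp, ref, alt, "misalignment_cluster", vaf,
                    gene.gene_id, cluster_id=cluster_id,
                )
            )

    records.sort(key=lambda r: r.pos)
    return records


def write_truth_tsv(records: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tpos\tref\talt\tclass\texpected_vaf\tgene_id\tcluster_id\n")
        for r in records:
            handle.write(
                f"{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}\t{r.class_label}\t"
                f"{r.expected_vaf}\t{r.gene_id or '.'}\t{r.cluster_id or '.'}\n"
            )


def read_truth_tsv(path: str) -> list[TruthRecord]:
    records = []
    with open(path) as handle:
        next(handle)
        for line in handle:
            c, p, ref, alt, cls, vaf, gid, cid = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    c, int(p), ref, alt, cls, float(vaf),
                    None if gid == "." else gid,
                    None if cid == "." else cid,
                )
            )
    return records


def write_population_vcf(
    records: Sequence[TruthRecord], path: str, chrom_length: int, af: float = 0.25
) -> None:
    """Population-database VCF holding the planted germline polymorphisms."""
    germline = sorted(
        (r for r in records if r.class_label == "germline_het"), key=lambda r: r.pos
    )
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n'
        )
        if germline:
            handle.write(f"##contig=<ID={germline[0].chrom},length={chrom_length}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in germline:
            handle.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t.\tAF={af}\n"
            )


def write_editing_db(
    records: Sequence[TruthRecord], path: str, known_fraction: float = 0.5
) -> None:
    """Known-editing-site table covering a deterministic subset of plants.

    Every other editing record (by position order) is 'known', emulating a
    database that catalogues only part of the editome; the strand rule must
    catch the rest.
    """
    editing = sorted(
        (r for r in records if r.class_label == "editing"), key=lambda r: r.pos
    )
    step = max(1, round(1 / known_fraction)) if known_fraction > 0 else len(editing) + 1
    with open(path, "w") as handle:
        handle.write("#chrom\tpos\n")
        for i, r in enumerate(editing):
            if known_fraction > 0 and i % step == 0:
                handle.write(f"{r.chrom}\t{r.pos}\n")


def _blocks_from_positions(positions: Sequence[int]) -> list[tuple[int, int]]:
    blocks = []
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
        else:
            blocks.append((start, prev))
            start = prev = p
    blocks.append((start, prev))
    return blocks


def _cigar_from_blocks(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            cig.append((3, s - blocks[i - 1][1] - 1))  # N
        cig.append((0, e - s + 1))  # M
    return cig


def simulate_reads(
    seed: int,
    genome: SyntheticGenome,
    truth: Sequence[TruthRecord],
    sam_path: str,
    depth: tuple[int, int] | int = (50, 200),
    read_len: int = 100,
    frag_len: int = 250,
    base_error: float = 1e-3,
    qc_decoy_fraction: float = 0.01,
) -> dict:
    """Simulate stranded paired-end reads over every gene and write SAM.

    Per-gene depth is drawn uniformly from ``depth`` (or fixed when a
    scalar).  Reads follow the dUTP convention: read 2 matches the gene
    strand.  A small fraction of fragments is re-emitted as QC decoys
    (duplicate-flagged, improper-pair, or low-MAPQ copies) to exercise
    read-level QC.  Output is coordinate-sorted SAM; identical seeds give
    byte-identical files.
    """
    rng = np.random.default_rng(seed)
    qual_char = chr(33 + max(2, round(-10 * np.log10(base_error)) if base_error > 0 else 60))
    by_gene: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        if rec.gene_id is not None:
            by_gene.setdefault(rec.gene_id, []).append(rec)

    reads = []  # (pos0, qname, flag, mapq, cigar, pnext0, tlen, seq, qual)

    def build_read(
        gpositions: Sequence[int],
        carriers: dict,
        forward: bool,
        gene_records: Sequence[TruthRecord],
    ) -> tuple[list[tuple[int, int]], str]:
        positions = sorted(gpositions)
        blocks = _blocks_from_positions(positions)
        seq = list("".join(genome.sequence[s - 1 : e] for s, e in blocks))
        index = {p: i for i, p in enumerate(positions)}
        for rec in gene_records:
            i = index.get(rec.pos)
            if i is None or not carriers.get(rec.key, False):
                continue
            if rec.strand_restricted and not forward:
                continue
            seq[i] = rec.alt
        if base_error > 0:
            errs = np.nonzero(rng.random(len(seq)) < base_error)[0]
            for i in errs:
                alts = [b for b in "ACGT" if b != seq[i]]
                seq[i] = alts[int(rng.integers(3))]
        return blocks, "".join(seq)

    n_pairs_total = 0
    for gene in genome.genes:
        tpos = genome.transcript_positions(gene)
        L = len(tpos)
        F = min(frag_len, L)
        if isinstance(depth, (tuple, list)):
            gene_depth = float(rng.uniform(depth[0], depth[1]))
        else:
            gene_depth = float(depth)
        span = L - F + 1
        covered = 2 * read_len if F >= 2 * read_len else F
        n_pairs = round(gene_depth * span / covered) if span > 0 and gene_depth > 0 else 0
        gene_records = by_gene.get(gene.gene_id, [])
        clusters: dict[str, list[TruthRecord]] = {}
        singles: list[TruthRecord] = []
        for rec in gene_records:
            if rec.cluster_id:
                clusters.setdefault(rec.cluster_id, []).append(rec)
            else:
                singles.append(rec)
        for pi in range(n_pairs):
            s = int(rng.integers(0, span))
            frag_pos = tpos[s : s + F]
            a_pos = frag_pos[:read_len]  # transcript 5' read = read 2
            b_pos = frag_pos[-read_len:]
            carriers: dict[tuple, bool] = {}
            frag_set = set(frag_pos)
            for rec in singles:
                if rec.pos in frag_set:
                    carriers[rec.key] = bool(rng.random() < rec.expected_vaf)
            for recs in clusters.values():
                if any(r.pos in frag_set for r in recs):
                    hit = bool(rng.random() < recs[0].expected_vaf)
                    for r in recs:
                        carriers[r.key] = hit
            a_fwd = gene.strand == "+"
            blocks_a, seq_a = build_read(a_pos, carriers, a_fwd, gene_records)
            blocks_b, seq_b = build_read(b_pos, carriers, not a_fwd, gene_records)
            qname = f"{gene.gene_id}:{pi}"
            left = min(blocks_a[0][0], blocks_b[0][0])
            right = max(blocks_a[-1][1], blocks_b[-1][1])
            span_len = right - left + 1
            if a_fwd:  # + gene: read A forward (read2), read B reverse (read1)
                flag_a, flag_b = 0x1 | 0x2 | 0x20 | 0x80, 0x1 | 0x2 | 0x10 | 0x40
            else:  # - gene: read A reverse (read2), read B forward (read1)
                flag_a, flag_b = 0x1 | 0x2 | 0x10 | 0x80, 0x1 | 0x2 | 0x20 | 0x40
            pos_a0 = blocks_a[0][0] - 1
            pos_b0 = blocks_b[0][0] - 1
            tlen_a = span_len if pos_a0 <= pos_b0 else -span_len
            reads.append(
                (pos_a0, qname, flag_a, 255, _cigar_from_blocks(blocks_a), pos_b0, tlen_a, seq_a)
            )
            reads.append(
                (pos_b0, qname, flag_b, 255, _cigar_from_blocks(blocks_b), pos_a0, -tlen_a, seq_b)
            )
            n_pairs_total += 1
            if qc_decoy_fraction > 0 and rng.random() < qc_decoy_fraction:
                kind = int(rng.integers(3))
                if kind == 0:  # duplicate-flagged copy
                    reads.append(
                        (pos_a0, qname + ":dup", flag_a | 0x400, 255,
                         _cigar_from_blocks(blocks_a), pos_b0, tlen_a, seq_a)
                    )
                elif kind == 1:  # improperly paired copy
                    reads.append(
                        (pos_a0, qname + ":imp", flag_a & ~0x2, 255,
                         _cigar_from_blocks(blocks_a), pos_b0, tlen_a, seq_a)
                    )
                else:  # ambiguous alignment (low MAPQ)
                    reads.append(
                        (pos_a0, qname + ":amb", flag_a, 3,
                         _cigar_from_blocks(blocks_a), pos_b0, tlen_a, seq_a)
                    )

    reads.sort(key=lambda r: (r[0], r[1], r[2]))
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.chrom, "LN": len(genome.sequence)}],
        }
    )
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for pos0, qname, flag, mapq, cigar, pnext0, tlen, seq in reads:
            aln = pysam.AlignedSegment(header)
            aln.query_name = qname
            aln.flag = flag
            aln.reference_id = 0
            aln.reference_start = pos0
            aln.mapping_quality = mapq
            aln.cigartuples = cigar
            aln.next_reference_id = 0
            aln.next_reference_start = pnext0
            aln.template_length = tlen
            aln.query_sequence = seq
            aln.query_qualities = pysam.qualitystring_to_array(qual_char * len(seq))
            out.write(aln)
    return {"n_pairs": n_pairs_total, "n_records": len(reads)}
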