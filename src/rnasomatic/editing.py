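"""RNA-editing and strand-asymmetric artifact filters.

A-to-I editing deaminates adenosine on the mRNA; sequencers read inosine as
G, so editing mimics A>G substitutions on the gene's sense strand.  In
genome coordinates that signature is A>G for a gene transcribed from the +
strand and T>C for a gene on the - strand.  8-oxo-guanine oxidation
produces the analogous strand-asymmetric G>T (+ gene) / C>A (- gene)
artifact common in post-mortem tissue; that rule set ships as an option
and is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .genotyper import Candidate

logger = logging.getLogger(__name__)

# (ref, alt, gene strand) triples in genome coordinates
EDITING_RULES = frozenset({("A", "G", "+"), ("T", "C", "-")})
OXOG_RULES = frozenset({("G", "T", "+"), ("C", "A", "-")})


@dataclass(slots=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted, non-overlapping

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def splice_junctions(self) -> list[int]:
        """Genomic positions flanking each intron (last/first exonic base)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.extend([e1, s2])
        return out

    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GeneIndex:
    """Interval lookup over gene spans and exons."""

    genes: list[GeneModel]
    _span_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _exon_trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for gene in self.genes:
            self._span_trees.setdefault(gene.chrom, IntervalTree()).addi(
                gene.start, gene.end + 1, gene
            )
            for s, e in gene.exons:
                self._exon_trees.setdefault(gene.chrom, IntervalTree()).addi(
                    s, e + 1, gene
                )

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._span_trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def exonic(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]


def load_gene_models(gtf_path: str) -> GeneIndex:
    """Load gene models from GTF/GFF exon features.

    Exons are grouped by ``gene_id`` (GTF attributes) and merged when they
    overlap; only the coordinates, strand and gene_id are retained.
    """
    import gffutils

    db = gffutils.create_db(
        gtf_path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, GeneModel] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", [exon.id])[0]
        model = by_gene.get(gid)
        if model is None:
            by_gene[gid] = GeneModel(
                gene_id=gid, chrom=exon.seqid, strand=exon.strand, exons=[(exon.start, exon.end)]
            )
        else:
            model.exons.append((exon.start, exon.end))
    for model in by_gene.values():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(model.exons):
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        model.exons = merged
    return GeneIndex(sorted(by_gene.values(), key=lambda g: (g.chrom, g.start)))


@dataclass
class EditingDB:
    """Known-editing-site table (DARNED/REDIportal style), 1-based positions."""

    sites: frozenset
    source_names: tuple[str, ...] = ()

    @classmethod
    def from_tsv(cls, path: str) -> "EditingDB":
        sites = set()
        with open(path) as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos = line.split("\t")[:2]
                sites.add((chrom, int(pos)))
        return cls(sites=frozenset(sites), source_names=(path,))

    @classmethod
    def from_vcf(cls, path: str) -> "EditingDB":
        import pysam

        sites = set()
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                sites.add((rec.chrom, rec.pos))
        return cls(sites=frozenset(sites), source_names=(path,))


def editing_db_filter(candidate: Candidate, db: EditingDB) -> bool:
    """Pass iff the candidate position is absent from the editing database."""
    return (candidate.chrom, candidate.pos) not in db.sites


def annotate_gene_context(candidate: Candidate, genes: GeneIndex) -> Candidate:
    candidate.gene_context = [
        (g.gene_id, g.strand, bool(genes.exonic(candidate.chrom, candidate.pos)))
        for g in genes.overlapping(candidate.chrom, candidate.pos)
    ]
    return candidate


def strand_rule_filter(
    candidate: Candidate,
    genes: GeneIndex,
    rules: frozenset = EDITING_RULES,
) -> bool:
    """Fail when the substitution matches a strand signature of any
    overlapping gene; intergenic candidates are exempt, and substitutions
    outside the rule set are never touched."""
    sub = (candidate.ref_base, candidate.alt_allele)
    for gene in genes.overlapping(candidate.chrom, candidate.pos):
        if (sub[0], sub[1], gene.strand) in rules:
            return False
    return True


def full_ag_tc_filter(candidate: Candidate) -> bool:
    """High-precision mode: drop every A>G / T>C regardless of gene context."""
    return (candidate.ref_base, candidate.alt_allele) not in {("A", "G"), ("T", "C")}


def exonic_filter(candidate: Candidate, genes: GeneIndex | None) -> bool:
    """Pass iff the position falls inside any annotated exon.

    With no annotation loaded the filter is disabled (always passes) and a
    warning is logged once per call site.
    """
    if genes is None:
        logger.warning("no gene annotation loaded; exonic filter disabled")
        return True
    return bool(genes.exonic(candidate.chrom, candidate.pos))
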