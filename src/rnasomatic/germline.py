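"""Germline separation and cross-sample recurrence filtering.

With matched DNA genotypes, candidates at DNA het/hom-alt sites are
germline; hom-ref sites with essentially no DNA alternate support are
somatic; uncovered sites stay unresolved and are kept with a flag.  Without
matched DNA, germline contamination is reduced by population polymorphism
databases (allele-aware matching) and a maximum RNA VAF, since germline
heterozygotes cluster near VAF 0.5.  Variants recurring across individuals
in a cohort are removed as presumptive shared artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pysam

from .genotyper import Candidate


@dataclass(slots=True)
class DnaEvidence:
    genotype: str  # hom_ref / het / hom_alt / missing
    dna_depth: int = 0
    dna_alt_count: int = 0

    @property
    def dna_vaf(self) -> float:
        return self.dna_alt_count / self.dna_depth if self.dna_depth else 0.0


class MatchedDnaGenotypes:
    """Genotypes from a matched whole-genome/exome VCF (first sample)."""

    def __init__(self, records: Mapping[tuple, DnaEvidence], contigs: frozenset):
        self._records = dict(records)
        self.contigs = contigs

    @classmethod
    def from_vcf(cls, path: str) -> "MatchedDnaGenotypes":
        records: dict[tuple, DnaEvidence] = {}
        contigs = set()
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                contigs.add(rec.chrom)
                sample = rec.samples[0] if rec.samples else None
                for alt in rec.alts or ():
                    key = (rec.chrom, rec.pos, rec.ref, alt)
                    gt = "missing"
                    depth = alt_count = 0
                    if sample is not None:
                        alleles = sample.get("GT") or ()
                        called = [a for a in alleles if a is not None]
                        if called:
                            alt_idx = (rec.alts or ()).index(alt) + 1
                            n_alt = sum(a == alt_idx for a in called)
                            if n_alt == 0:
                                gt = "hom_ref"
                            elif n_alt == len(called):
                                gt = "hom_alt"
                            else:
                                gt = "het"
                        depth = int(sample.get("DP") or 0)
                        ad = sample.get("AD")
                        if ad is not None:
                            alt_idx = (rec.alts or ()).index(alt) + 1
                            if len(ad) > alt_idx and ad[alt_idx] is not None:
                                alt_count = int(ad[alt_idx])
                    records[key] = DnaEvidence(gt, depth, alt_count)
        return cls(records, frozenset(contigs))

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> DnaEvidence:
        if self.contigs and chrom not in self.contigs:
            raise ValueError(
                f"contig {chrom!r} absent from matched DNA VCF (contigs "
                f"{sorted(self.contigs)[:5]}...); remap contig names to match"
            )
        return self._records.get((chrom, pos, ref, alt), DnaEvidence("missing"))


def germline_subtract(
    candidate: Candidate,
    dna: MatchedDnaGenotypes,
    dna_vaf_somatic_max: float = 0.02,
) -> str:
    """Classify a candidate as somatic / germline / unresolved from DNA.

    het or hom_alt DNA genotype -> germline; hom_ref with DNA VAF at or
    below ``dna_vaf_somatic_max`` -> somatic (absent in control); anything
    else (missing, or hom_ref with suspicious DNA alternate support) ->
    unresolved, kept but flagged.
    """
    ev = dna.lookup(candidate.chrom, candidate.pos, candidate.ref_base, candidate.alt_allele)
    if ev.genotype in ("het", "hom_alt"):
        return "germline"
    if ev.genotype == "hom_ref":
        return "somatic" if ev.dna_vaf <= dna_vaf_somatic_max else "unresolved"
    return "unresolved"


class SnpFrequencyDb:
    """Population polymorphism database: allele-aware presence + frequency.

    Loads a VCF into memory keyed by (chrom, pos, ref, alt); the AF INFO
    field (first value) provides the population alternate-allele frequency
    used by the genotyper's priors.  Records without AF are stored with
    frequency None.
    """

    def __init__(self, entries: Mapping[tuple, float | None] | None = None):
        self._entries: dict[tuple, float | None] = dict(entries or {})

    @classmethod
    def from_vcf(cls, path: str) -> "SnpFrequencyDb":
        entries: dict[tuple, float | None] = {}
        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                af = rec.info.get("AF") if "AF" in rec.info else None
                if isinstance(af, (tuple, list)):
                    afs = list(af)
                else:
                    afs = [af] * len(rec.alts or ())
                for alt, freq in zip(rec.alts or (), afs):
                    entries[(rec.chrom, rec.pos, rec.ref, alt)] = (
                        float(freq) if freq is not None else None
                    )
        return cls(entries)

    def __contains__(self, key: tuple) -> bool:
        return key in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def allele_frequency(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        return self._entries.get((chrom, pos, ref, alt))


def population_db_filter(candidate: Candidate, dbs: Iterable[SnpFrequencyDb]) -> bool:
    """Pass iff (chrom, pos, ref, alt) is absent from every population DB."""
    key = candidate.key
    return not any(key in db for db in dbs)


def max_vaf_filter(candidate: Candidate, max_vaf: float = 0.5) -> bool:
    """No-matched-DNA mode: pass iff RNA VAF <= ``max_vaf`` (boundary passes)."""
    return candidate.vaf <= max_vaf


@dataclass
class CohortIndex:
    """Which individuals carry each variant; tissues of one donor collapse."""

    occurrence: dict[tuple, set] = field(default_factory=dict)

    def add_call_set(self, individual_id: str, keys: Iterable[tuple]) -> None:
        for key in keys:
            self.occurrence.setdefault(key, set()).add(individual_id)

    @classmethod
    def from_tsv(cls, path: str) -> "CohortIndex":
        index = cls()
        with open(path) as handle:
            for line in handle:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos, ref, alt, ids = line.rstrip("\n").split("\t")[:5]
                key = (chrom, int(pos), ref, alt)
                index.occurrence.setdefault(key, set()).update(ids.split(","))
        return index

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as handle:
            for key in sorted(self.occurrence):
                ids = ",".join(sorted(self.occurrence[key]))
                handle.write("\t".join([key[0], str(key[1]), key[2], key[3], ids]) + "\n")


def recurrence_filter(index: CohortIndex, max_individuals: int = 1) -> dict[tuple, bool]:
    """Verdict per variant key: fail when carried by more than
    ``max_individuals`` distinct individuals (strictly greater).  The
    default of 1 removes any cross-individual sharing; cohort analyses of
    brain tissue use 2 ("more than two individuals").  Multiple tissues of
    one individual never trigger the filter because occurrence is keyed by
    individual, not sample.
    """
    return {
        key: len(individuals) <= max_individuals
        for key, individuals in index.occurrence.items()
    }
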