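"""End-to-end orchestration: genotyper -> artifact filters -> editing
filters -> germline separation, with a complete per-candidate audit trail.

Stage order mirrors the calling design: pileups are genotyped first, the
nominated candidates then accumulate filter verdicts (pure predicates, so
their order is bookkeeping, not semantics), and germline separation runs
last.  Every candidate appears in the TSV with all verdicts; the VCF keeps
all-pass calls, plus editing-flagged records when ``flag_only`` is set.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field

import pyfaidx
import pysam

from . import editing as ed
from . import filters as flt
from . import germline as gl
from .benchmark import PoweredRegion, powered_from_positions
from .config import PipelineConfig
from .genotyper import (
    Candidate,
    GenotypeModel,
    compute_posteriors,
    pick_alt_allele,
    select_candidates,
)
from .pileup import (
    QcConfig,
    ReferenceLookup,
    annotate_read_end_flags,
    build_pileups,
    load_reads,
)

logger = logging.getLogger(__name__)

BIAS_ATTRIBUTES = ("strand", "mapq", "read_position")


@dataclass
class PipelineResult:
    candidates: list[Candidate]
    powered: PoweredRegion
    stage_counts: dict = field(default_factory=dict)

    @property
    def calls(self) -> list[Candidate]:
        return [c for c in self.candidates if c.passes_all]

    def call_keys(self) -> set:
        return {c.key for c in self.calls}


def _genotype_and_nominate(config: PipelineConfig, reference, snp_dbs):
    qc = QcConfig(min_mapq=config.min_mapq, single_end=config.single_end)
    model = GenotypeModel(
        p_m=config.p_m,
        default_p_alt=config.default_p_alt,
        quadrature_points=config.quadrature_points,
    )
    lookup = ReferenceLookup(reference)
    snp_db = snp_dbs[0] if snp_dbs else None

    powered_positions: list[tuple[str, int]] = []

    def posterior_stream():
        reads = load_reads(config.alignment, region=config.region, qc_config=qc)
        for site in build_pileups(
            reads, lookup, min_depth=config.min_depth,
            count_n_in_depth=config.count_n_in_depth,
        ):
            powered_positions.append((site.chrom, site.pos))
            _, alt_count, _ = pick_alt_allele(site)
            if alt_count == 0:
                continue  # hom_ref-dominated; cannot be nominated
            yield site, compute_posteriors(site, model, snp_db)

    candidates = list(
        select_candidates(posterior_stream(), config.min_candidate_posterior)
    )
    return candidates, powered_from_positions(powered_positions)


def _apply_multiallelic(candidates, config):
    for cand in candidates:
        _, _, second = pick_alt_allele(cand.site)
        cand.record(
            "multiallelic", second / cand.depth <= config.multiallelic_max_second_vaf
        )


def _apply_realignment(candidates, config, reference):
    """Second pass over the alignment file: verify reads at candidate sites."""
    verifier = flt.RealignmentVerifier(
        match=config.realign_match,
        mismatch=config.realign_mismatch,
        gap_open=config.realign_gap_open,
        gap_extend=config.realign_gap_extend,
        min_margin=config.realign_min_margin,
    )
    by_chrom: dict[str, list[int]] = {}
    for cand in candidates:
        by_chrom.setdefault(cand.chrom, []).append(cand.pos)
    for positions in by_chrom.values():
        positions.sort()
    confirmed: dict[str, bool] = {}
    seqs = {chrom: str(reference[chrom]).upper() for chrom in by_chrom}
    qc = QcConfig(min_mapq=config.min_mapq, single_end=config.single_end)
    for read in load_reads(config.alignment, region=config.region, qc_config=qc):
        positions = by_chrom.get(read.chrom)
        if not positions:
            continue
        lo = bisect.bisect_left(positions, read.start)
        if lo >= len(positions) or positions[lo] > read.end:
            continue
        confirmed[read.read_id] = flt.realignment_verify(
            read, {read.chrom: seqs[read.chrom]}, verifier
        )
    for cand in candidates:
        for obs in cand.site.observations:
            obs.realignment_confirmed = confirmed.get(obs.read_id, False)


def _apply_empirical(candidates, config, masks):
    linkage = flt.linkage_filter(
        candidates,
        min_shared=config.linkage_min_shared,
        window_bp=config.linkage_window_bp,
    )
    for cand in candidates:
        cand.record(
            "depth_vaf",
            flt.depth_vaf_filter(cand, config.min_vaf, config.min_alt_reads),
        )
        cand.record("region_mask", flt.region_mask_filter(cand, masks))
        for attribute in BIAS_ATTRIBUTES:
            result = flt.allele_bias_filter(
                cand, cand.site, attribute, alpha=config.bias_alpha
            )
            cand.record(f"bias_{attribute}", result.verdict == "pass")
        cand.record("linkage", linkage[cand.key])
        cand.record(
            "hq_fraction",
            flt.hq_fraction_filter(cand, cand.site, config.hq_min_fraction),
        )


EDITING_FILTERS = ("editing_db", "strand_rule", "full_ag_tc", "oxo_g", "exonic")


def _apply_editing(candidates, config, genes, editing_db):
    for cand in candidates:
        if genes is not None:
            ed.annotate_gene_context(cand, genes)
        if editing_db is not None:
            cand.record("editing_db", ed.editing_db_filter(cand, editing_db))
        if config.editing_mode == "full_ag_tc":
            cand.record("full_ag_tc", ed.full_ag_tc_filter(cand))
        elif genes is not None:
            cand.record(
                "strand_rule", ed.strand_rule_filter(cand, genes, ed.EDITING_RULES)
            )
        if config.oxo_g_mode and genes is not None:
            cand.record("oxo_g", ed.strand_rule_filter(cand, genes, ed.OXOG_RULES))
        cand.record("exonic", ed.exonic_filter(cand, genes))


def _apply_germline(candidates, config, snp_dbs, matched_dna):
    for cand in candidates:
        if matched_dna is not None:
            status = gl.germline_subtract(cand, matched_dna, config.dna_vaf_somatic_max)
            cand.record("germline_dna", status != "germline")
            cand.germline_status = status
        else:
            cand.record("max_vaf", gl.max_vaf_filter(cand, config.max_vaf))
        if snp_dbs:
            cand.record("population_db", gl.population_db_filter(cand, snp_dbs))


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    if config.alignment is None or config.reference is None:
        raise ValueError("config must provide 'alignment' and 'reference' paths")
    reference = pyfaidx.Fasta(config.reference, sequence_always_upper=True)
    genes = ed.load_gene_models(config.genes_gtf) if config.genes_gtf else None
    editing_db = None
    if config.editing_db:
        loader = (
            ed.EditingDB.from_vcf
            if config.editing_db.endswith((".vcf", ".vcf.gz"))
            else ed.EditingDB.from_tsv
        )
        editing_db = loader(config.editing_db)
    snp_dbs = [gl.SnpFrequencyDb.from_vcf(p) for p in config.population_vcfs]
    matched_dna = (
        gl.MatchedDnaGenotypes.from_vcf(config.matched_dna_vcf)
        if config.matched_dna_vcf
        else None
    )

    candidates, powered = _genotype_and_nominate(config, reference, snp_dbs)
    logger.info("nominated %d candidates", len(candidates))

    for cand in candidates:
        annotate_read_end_flags(cand.site, config.near_end_bp, config.near_junction_bp)
    _apply_realignment(candidates, config, reference)

    masks = [
        flt.homopolymer_scan(
            ((name, str(reference[name])) for name in reference.keys()),
            min_run=config.homopolymer_min_run,
            pad_bp=config.homopolymer_pad,
        )
    ]
    if config.repeat_bed:
        masks.append(flt.RegionMask.from_bed(config.repeat_bed))

    _apply_multiallelic(candidates, config)
    _apply_empirical(candidates, config, masks)
    _apply_editing(candidates, config, genes, editing_db)
    _apply_germline(candidates, config, snp_dbs, matched_dna)

    stage_counts = _stage_counts(candidates)
    logger.info(
        "filter stages: %s",
        ", ".join(f"{k}={v}" for k, v in stage_counts["removed_by"].items()),
    )
    return PipelineResult(candidates=candidates, powered=powered, stage_counts=stage_counts)


def _stage_counts(candidates) -> dict:
    removed_by: dict[str, int] = {}
    survivors = 0
    for cand in candidates:
        first = cand.first_failed
        if first is None:
            survivors += 1
        else:
            removed_by[first] = removed_by.get(first, 0) + 1
    return {
        "n_candidates": len(candidates),
        "removed_by": removed_by,
        "survivors": survivors,
    }


EDITING_FLAG_FILTERS = {"editing_db", "strand_rule", "full_ag_tc", "oxo_g"}


def _vcf_header(config: PipelineConfig, contigs) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.info.add("DP", 1, "Integer", "Read depth at the site")
    header.info.add("AC", "A", "Integer", "Alternate-supporting read count")
    header.info.add("AF", "A", "Float", "Variant allele fraction")
    header.info.add("PHOM", 1, "Float", "Posterior of homozygous-reference genotype")
    header.info.add("PHET", 1, "Float", "Posterior of heterozygous genotype")
    header.info.add("PALT", 1, "Float", "Posterior of homozygous-alternate genotype")
    header.info.add("PMOS", 1, "Float", "Posterior of mosaic genotype")
    header.filters.add("editing_flagged", None, None, "Editing filter hit (flag-only mode)")
    return header


def write_outputs(
    result: PipelineResult,
    config: PipelineConfig,
    vcf_path: str,
    tsv_path: str,
    summary_path: str | None = None,
) -> None:
    """Write the calls VCF, the full audit TSV, and a summary JSON."""
    reference = pyfaidx.Fasta(config.reference)
    contigs = [(name, len(reference[name])) for name in reference.keys()]
    header = _vcf_header(config, contigs)
    ordered = sorted(result.candidates, key=lambda c: (c.chrom, c.pos, c.alt_allele))
    with pysam.VariantFile(vcf_path, "w", header=header) as vcf:
        for cand in ordered:
            failed = [
                name
                for name, verdict in cand.filter_verdicts.items()
                if verdict == "fail"
            ]
            if failed and not (
                config.flag_only and set(failed) <= EDITING_FLAG_FILTERS
            ):
                continue
            rec = vcf.new_record(
                contig=cand.chrom,
                start=cand.pos - 1,
                stop=cand.pos,
                alleles=(cand.ref_base, cand.alt_allele),
            )
            rec.info["DP"] = cand.depth
            rec.info["AC"] = cand.alt_count
            rec.info["AF"] = round(cand.vaf, 6)
            post = cand.posterior.probs
            rec.info["PHOM"] = round(post["hom_ref"], 6)
            rec.info["PHET"] = round(post["het"], 6)
            rec.info["PALT"] = round(post["hom_alt"], 6)
            rec.info["PMOS"] = round(post["mosaic"], 6)
            if failed:
                rec.filter.add("editing_flagged")
            else:
                rec.filter.add("PASS")
            vcf.write(rec)

    verdict_names: list[str] = []
    for cand in ordered:
        for name in cand.filter_verdicts:
            if name not in verdict_names:
                verdict_names.append(name)
    with open(tsv_path, "w") as tsv:
        head = [
            "chrom", "pos", "ref", "alt", "depth", "alt_count", "vaf",
            "p_hom_ref", "p_het", "p_hom_alt", "p_mosaic",
        ] + verdict_names + ["final"]
        tsv.write("\t".join(head) + "\n")
        for cand in ordered:
            post = cand.posterior.probs
            row = [
                cand.chrom, str(cand.pos), cand.ref_base, cand.alt_allele,
                str(cand.depth), str(cand.alt_count), f"{cand.vaf:.6f}",
                f"{post['hom_ref']:.6g}", f"{post['het']:.6g}",
                f"{post['hom_alt']:.6g}", f"{post['mosaic']:.6g}",
            ]
            row += [cand.filter_verdicts.get(name, ".") for name in verdict_names]
            row.append("PASS" if cand.passes_all else (cand.first_failed or "FAIL"))
            tsv.write("\t".join(row) + "\n")

    if summary_path is not None:
        summary = {
            "sample_id": config.sample_id,
            "stage_counts": result.stage_counts,
            "powered_bp": result.powered.total_bp,
            "n_calls": len(result.calls),
        }
        with open(summary_path, "w") as handle:
            json.dump(summary, handle, indent=2, sort_keys=True)
            handle.write("\n")
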