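"""Synthetic-data generator: determinism, layout, planted allele fractions."""

import collections
import math
from pathlib import Path

import numpy as np
import pysam
import pytest

from rnasomatic import simulate as sim


SIX_LINE_MIX = [
    ("L1", 0.45), ("L2", 0.20), ("L3", 0.10),
    ("L4", 0.10), ("L5", 0.10), ("L6", 0.05),
]


class TestReferenceAndGenes:
    def test_same_seed_identical_fasta(self, tmp_path):
        a = sim.generate_reference_and_genes(7, n_genes=4, chrom_length=40_000)
        b = sim.generate_reference_and_genes(7, n_genes=4, chrom_length=40_000)
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        sim.write_fasta(a, pa)
        sim.write_fasta(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_gene_count_and_alternating_strands(self):
        genome = sim.generate_reference_and_genes(7, n_genes=4, chrom_length=40_000)
        assert [g.strand for g in genome.genes] == ["+", "-", "+", "-"]
        for gene in genome.genes:
            spans = [s for s, _ in gene.exons]
            assert spans == sorted(spans)
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                assert s2 - e1 - 1 >= 60  # introns at least 60 bp

    def test_gc_fraction_concentrates(self):
        genome = sim.generate_reference_and_genes(
            3, n_genes=1, chrom_length=10_000, gc=0.5, duplicate_segment=False
        )
        gc = sum(b in "GC" for b in genome.sequence) / len(genome.sequence)
        assert 0.45 <= gc <= 0.55  # binomial concentration at n = 10^4


class TestMixtureDesign:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sim.MixtureDesign(lines=[("L1", 0.5), ("L2", 0.4)])

    @pytest.mark.parametrize(
        "copies_by_line,expected",
        [
            ({"L1": 1}, 0.225),  # het in the 45% line only
            ({"L6": 2}, 0.05),  # hom-alt in the 5% line only
            ({f"L{i}": 1 for i in range(1, 7)}, 0.5),  # het in all six lines
        ],
    )
    def test_expected_vaf_arithmetic(self, copies_by_line, expected):
        key = ("chr1", 100, "A", "G")
        design = sim.MixtureDesign(
            lines=SIX_LINE_MIX,
            genotypes={(line, key): c for line, c in copies_by_line.items()},
        )
        assert design.expected_vaf(key) == pytest.approx(expected)

    def test_mixture_mode_sets_germline_vafs(self):
        genome = sim.generate_reference_and_genes(5, n_genes=4, chrom_length=60_000)
        mix = sim.MixtureDesign(lines=SIX_LINE_MIX)
        design = sim.TruthDesign(
            n_mosaic=0, n_germline_het=5, n_editing=0, n_oxog=0,
            n_strand_bias=0, n_misalignment_clusters=0, mixture=mix,
        )
        truth = sim.plant_truth(6, genome, design)
        # no genotypes registered -> expected VAF 0 for every surrogate
        assert all(r.expected_vaf == 0.0 for r in truth)


class TestPlanting:
    def test_classes_and_counts(self, e2e_dataset):
        counts = collections.Counter(r.class_label for r in e2e_dataset["truth"])
        design = sim.TruthDesign()
        assert counts["mosaic"] == design.n_mosaic
        assert counts["editing"] == design.n_editing
        assert counts["misalignment_cluster"] == 3 * design.n_misalignment_clusters

    def test_editing_signatures_match_gene_strand(self, e2e_dataset):
        strands = {g.gene_id: g.strand for g in e2e_dataset["genome"].genes}
        for rec in e2e_dataset["truth"]:
            if rec.class_label == "editing":
                expected = ("A", "G") if strands[rec.gene_id] == "+" else ("T", "C")
                assert (rec.ref, rec.alt) == expected

    def test_positions_unique_and_ref_consistent(self, e2e_dataset):
        seqs = e2e_dataset["genome"].sequence
        positions = [r.pos for r in e2e_dataset["truth"]]
        assert len(set(positions)) == len(positions)
        for rec in e2e_dataset["truth"]:
            assert seqs[rec.pos - 1] == rec.ref != rec.alt


def _empirical_vaf(sam_path, chrom, pos, alt):
    alt_n = total = 0
    with pysam.AlignmentFile(sam_path, "r") as handle:
        for aln in handle:
            if aln.reference_start >= pos or (aln.reference_end or 0) < pos:
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if rpos == pos - 1:
                    total += 1
                    alt_n += aln.query_sequence[qpos] == alt
    return alt_n, total


class TestReads:
    def test_same_seed_byte_identical_sam(self, tmp_path):
        genome = sim.generate_reference_and_genes(9, n_genes=3, chrom_length=30_000)
        truth = sim.plant_truth(10, genome, sim.TruthDesign(
            n_mosaic=2, n_germline_het=2, n_editing=2, n_oxog=0,
            n_strand_bias=0, n_misalignment_clusters=0))
        pa, pb = tmp_path / "a.sam", tmp_path / "b.sam"
        sim.simulate_reads(11, genome, truth, str(pa), depth=40)
        sim.simulate_reads(11, genome, truth, str(pb), depth=40)
        assert pa.read_bytes() == pb.read_bytes()

    def test_error_free_unplanted_pileup_is_pure_reference(self, tmp_path):
        genome = sim.generate_reference_and_genes(9, n_genes=2, chrom_length=20_000)
        path = tmp_path / "clean.sam"
        sim.simulate_reads(12, genome, [], str(path), depth=30, base_error=0.0,
                          qc_decoy_fraction=0.0)
        with pysam.AlignmentFile(str(path), "r") as handle:
            for aln in handle:
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                    assert aln.query_sequence[qpos] == genome.sequence[rpos]

    def test_zero_depth_gives_empty_sam_with_header(self, tmp_path):
        genome = sim.generate_reference_and_genes(9, n_genes=2, chrom_length=20_000)
        path = tmp_path / "empty.sam"
        sim.simulate_reads(13, genome, [], str(path), depth=0)
        with pysam.AlignmentFile(str(path), "r") as handle:
            assert handle.header.nreferences == 1
            assert sum(1 for _ in handle) == 0

    def test_planted_vaf_concentrates_at_high_depth(self, tmp_path):
        """Empirical VAF approaches the planted fraction (3 sigma binomial)."""
        genome = sim.generate_reference_and_genes(
            21, n_genes=1, chrom_length=20_000, duplicate_segment=False
        )
        design = sim.TruthDesign(
            n_mosaic=1, mosaic_vaf=(0.2, 0.2), n_germline_het=0, n_editing=0,
            n_oxog=0, n_strand_bias=0, n_misalignment_clusters=0,
        )
        truth = sim.plant_truth(22, genome, design)
        (rec,) = truth
        path = tmp_path / "deep.sam"
        sim.simulate_reads(23, genome, truth, str(path), depth=5000,
                          base_error=0.0, qc_decoy_fraction=0.0)
        alt_n, total = _empirical_vaf(str(path), rec.chrom, rec.pos, rec.alt)
        assert total > 3000
        sigma = math.sqrt(rec.expected_vaf * (1 - rec.expected_vaf) / total)
        assert abs(alt_n / total - rec.expected_vaf) <= 3 * sigma

    def test_junction_spanning_cigars_present(self, small_dataset):
        with pysam.AlignmentFile(small_dataset["sam"], "r") as handle:
            assert any("N" in (aln.cigarstring or "") for aln in handle)
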