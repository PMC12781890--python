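"""Shared fixtures: in-memory pileup factories and seeded synthetic datasets."""

from __future__ import annotations

import math
from pathlib import Path

import pytest

from rnasomatic import simulate as sim
from rnasomatic.config import PipelineConfig
from rnasomatic.pileup import Observation, PileupSite


def make_site(
    n_ref: int,
    n_alt: int,
    qual: int = 30,
    ref: str = "A",
    alt: str = "G",
    chrom: str = "chr1",
    pos: int = 100,
    ref_strands=None,
    alt_strands=None,
    ref_mapq: int = 60,
    alt_mapq: int = 60,
    ref_dist_end: int = 25,
    alt_dist_end: int = 25,
) -> PileupSite:
    """Site with ``n_ref`` reference and ``n_alt`` alternate observations."""
    obs = []
    for i in range(n_ref):
        strand = ref_strands[i] if ref_strands else ("+" if i % 2 == 0 else "-")
        obs.append(
            Observation(ref, qual, strand, ref_mapq, ref_dist_end, math.inf,
                        f"ref{i}/1", f"ref{i}")
        )
    for i in range(n_alt):
        strand = alt_strands[i] if alt_strands else ("+" if i % 2 == 0 else "-")
        obs.append(
            Observation(alt, qual, strand, alt_mapq, alt_dist_end, math.inf,
                        f"alt{i}/1", f"alt{i}")
        )
    return PileupSite(chrom, pos, ref, obs)


def _write_dataset(root: Path, seed: int, n_genes: int, chrom_length: int,
                   design: sim.TruthDesign, depth) -> dict:
    root.mkdir(parents=True, exist_ok=True)
    genome = sim.generate_reference_and_genes(
        seed, n_genes=n_genes, chrom_length=chrom_length
    )
    truth = sim.plant_truth(seed + 1, genome, design)
    paths = {name: str(root / fname) for name, fname in [
        ("fasta", "reference.fa"), ("gtf", "genes.gtf"), ("sam", "reads.sam"),
        ("truth_tsv", "truth.tsv"), ("population_vcf", "population.vcf"),
        ("editing_db", "editing_db.tsv"),
    ]}
    sim.write_fasta(genome, paths["fasta"])
    sim.write_gtf(genome, paths["gtf"])
    sim.write_truth_tsv(truth, paths["truth_tsv"])
    sim.write_population_vcf(truth, paths["population_vcf"], len(genome.sequence))
    sim.write_editing_db(truth, paths["editing_db"])
    sim.simulate_reads(seed + 2, genome, truth, paths["sam"], depth=depth)
    return {"genome": genome, "truth": truth, "seed": seed, "depth": depth, **paths}


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory) -> dict:
    """Compact dataset (10 genes, 120 kb) for fast pipeline-level tests."""
    design = sim.TruthDesign(
        n_mosaic=8, n_germline_het=8, n_editing=12, n_oxog=4,
        n_strand_bias=4, n_misalignment_clusters=2,
    )
    return _write_dataset(
        tmp_path_factory.mktemp("small"), seed=101, n_genes=10,
        chrom_length=120_000, design=design, depth=(60, 120),
    )


def dataset_config(ds: dict, **overrides) -> PipelineConfig:
    base = dict(
        alignment=ds["sam"],
        reference=ds["fasta"],
        genes_gtf=ds["gtf"],
        editing_db=ds["editing_db"],
        population_vcfs=[ds["population_vcf"]],
    )
    base.update(overrides)
    return PipelineConfig(**base).validate()


@pytest.fixture(scope="session")
def e2e_dataset(tmp_path_factory) -> dict:
    """Benchmark-scale dataset: 1 Mb, 40 genes, default planted design."""
    return _write_dataset(
        tmp_path_factory.mktemp("e2e"), seed=42, n_genes=40,
        chrom_length=1_000_000, design=sim.TruthDesign(), depth=(50, 200),
    )


@pytest.fixture(scope="session")
def e2e_result(e2e_dataset):
    """Default pipeline over the benchmark dataset.

    The oxidation rule set is enabled because the dataset plants 8-oxo-G
    artifacts (the configuration recommended for oxidation-affected
    samples); everything else is the package default.
    """
    from rnasomatic.pipeline import run_pipeline

    config = dataset_config(e2e_dataset, oxo_g_mode=True)
    return run_pipeline(config), config
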