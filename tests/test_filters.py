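"""Empirical filters: thresholds, bias tests, linkage, realignment, HQ support."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from rnasomatic.filters import (
    RealignmentVerifier,
    RegionMask,
    allele_bias_filter,
    depth_vaf_filter,
    fisher_exact_two_sided,
    homopolymer_scan,
    hq_fraction_filter,
    linkage_filter,
    realignment_verify,
    region_mask_filter,
)
from rnasomatic.genotyper import Candidate, GenotypePosterior
from rnasomatic.pileup import ReadRecord

from conftest import make_site


def _candidate(depth, alt_count, chrom="chr1", pos=100, ref="A", alt="G", site=None):
    post = GenotypePosterior(
        probs={"hom_ref": 0.0, "het": 0.5, "hom_alt": 0.0, "mosaic": 0.5},
        alt_allele=alt,
        log_likelihoods={},
    )
    return Candidate(chrom, pos, ref, alt, depth, alt_count,
                     alt_count / depth if depth else 0.0, post, site=site)


class TestDepthVaf:
    @pytest.mark.parametrize(
        "depth,alt,expect",
        [
            (100, 5, True),  # exactly 5% VAF and 5 reads: boundary passes
            (100, 4, False),  # fewer than 5 supporting reads
            (20, 1, False),  # 5% VAF but a single supporting read
            (200, 9, False),  # 9 reads but VAF 4.5%
            (40, 6, True),
        ],
    )
    def test_boundaries_are_strict_less_than(self, depth, alt, expect):
        assert depth_vaf_filter(_candidate(depth, alt)) is expect


class TestRegionMasks:
    def test_single_run_masked_with_padding(self):
        mask = homopolymer_scan({"chr1": "ACGTAAAAACGT"}, min_run=5, pad_bp=1)
        masked = [p for p in range(1, 13) if mask.contains("chr1", p)]
        assert masked == [4, 5, 6, 7, 8, 9, 10]

    def test_no_runs_no_mask(self):
        assert homopolymer_scan({"chr1": "ACGTACGT"}).total_bp() == 0

    def test_run_shorter_than_min_ignored(self):
        assert homopolymer_scan({"chr1": "AAAA"}, min_run=5).total_bp() == 0

    def test_region_mask_filter_verdicts(self):
        mask = RegionMask.from_intervals([("chr1", 90, 110)], source="repeat_bed")
        assert not region_mask_filter(_candidate(50, 10, pos=100), [mask])
        assert region_mask_filter(_candidate(50, 10, pos=200), [mask])
        assert region_mask_filter(_candidate(50, 10, pos=100), [])


class TestBiasTests:
    def test_identical_strand_proportions_pass(self):
        site = make_site(100, 10, ref_strands=["+", "-"] * 50,
                         alt_strands=["+", "-"] * 5)
        res = allele_bias_filter(_candidate(110, 10), site, "strand")
        assert res.p_value == pytest.approx(1.0) and res.verdict == "pass"

    def test_one_sided_alt_strand_fails(self):
        site = make_site(100, 10, ref_strands=["+", "-"] * 50,
                         alt_strands=["+"] * 10)
        res = allele_bias_filter(_candidate(110, 10), site, "strand")
        _, p_oracle = scipy_fisher([[50, 50], [10, 0]])
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)
        assert res.verdict == "fail"

    def test_identical_mapq_distributions_pass(self):
        site = make_site(60, 10, ref_mapq=60, alt_mapq=60)
        res = allele_bias_filter(_candidate(70, 10), site, "mapq")
        assert res.p_value == 1.0 and res.verdict == "pass"

    def test_read_position_bias_fails(self):
        site = make_site(60, 10, ref_dist_end=40, alt_dist_end=1)
        res = allele_bias_filter(_candidate(70, 10), site, "read_position")
        assert res.verdict == "fail"

    def test_untestable_site_passes(self):
        site = make_site(20, 0)
        res = allele_bias_filter(_candidate(20, 0), site, "strand")
        assert res.verdict == "pass" and not res.testable

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(cells=st.lists(st.integers(0, 25), min_size=4, max_size=4))
    def test_fisher_matches_scipy(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        _, mine = fisher_exact_two_sided([[a, b], [c, d]])
        _, ref = scipy_fisher([[a, b], [c, d]])
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_fisher_symmetries(self):
        table = [[12, 3], [4, 9]]
        base = fisher_exact_two_sided(table)[1]
        assert fisher_exact_two_sided([table[1], table[0]])[1] == pytest.approx(base)
        assert fisher_exact_two_sided(
            [[12, 4], [3, 9]]
        )[1] == pytest.approx(base)  # transpose


def _linked_candidates(pattern_b):
    """Two candidates at pos 100/140; alt carriers at A are pairs p0-p2."""
    site_a = make_site(20, 0, pos=100)
    site_b = make_site(20, 0, pos=140)
    for i in range(3):
        site_a.observations[i].base = "G"
    for i, carries in enumerate(pattern_b):
        if carries:
            site_b.observations[i].base = "G"
    a = _candidate(20, 3, pos=100, site=site_a)
    b = _candidate(20, sum(pattern_b), pos=140, site=site_b)
    return a, b


class TestLinkage:
    def test_complete_linkage_fails_both(self):
        a, b = _linked_candidates([1, 1, 1])
        verdicts = linkage_filter([a, b])
        assert verdicts[a.key] is False and verdicts[b.key] is False

    def test_incomplete_linkage_passes(self):
        # pair ref2 covers B with the reference base
        a, b = _linked_candidates([1, 1, 0])
        verdicts = linkage_filter([a, b])
        assert verdicts[a.key] is True and verdicts[b.key] is True

    def test_isolated_candidate_passes(self):
        site = make_site(20, 5, pos=100)
        cand = _candidate(20, 5, site=site)
        assert linkage_filter([cand])[cand.key] is True

    def test_distant_candidates_not_compared(self):
        a, b = _linked_candidates([1, 1, 1])
        b.pos = b.site.pos = 100 + 5000
        verdicts = linkage_filter([a, b], window_bp=1000)
        assert verdicts[a.key] is True and verdicts[b.key] is True


class TestRealignment:
    def _read(self, seq, start, chrom="chr1"):
        return ReadRecord("r/1", "r", chrom, [(start, start + len(seq) - 1)],
                          "+", 60, True, True, False, seq, [30] * len(seq))

    def test_unique_perfect_match_confirmed(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), 400))
        read = self._read(ref[100:150], 101)
        assert realignment_verify(read, {"chr1": ref})

    def test_tandem_duplicate_rejected(self):
        rng = np.random.default_rng(1)
        unit = "".join(rng.choice(list("ACGT"), 80))
        ref = "".join(rng.choice(list("ACGT"), 100)) + unit + unit + "".join(
            rng.choice(list("ACGT"), 100)
        )
        read = self._read(unit[10:60], 111)  # matches both copies equally
        assert not realignment_verify(read, {"chr1": ref})

    def test_mismatches_with_clear_margin_confirmed(self):
        rng = np.random.default_rng(2)
        ref = "".join(rng.choice(list("ACGT"), 400))
        seq = list(ref[100:150])
        seq[10] = "A" if seq[10] != "A" else "C"
        seq[30] = "A" if seq[30] != "A" else "C"
        read = self._read("".join(seq), 101)
        # claimed locus scores 50 - 2*3 = 44; random next-best far lower
        assert realignment_verify(read, {"chr1": ref})

    def test_scoring_margins_by_hand(self):
        v = RealignmentVerifier()
        # claimed: 2 mismatches in 50 bp -> 44; alternative scores 34
        claimed = "A" * 50
        read = "A" * 20 + "C" + "A" * 9 + "C" + "A" * 19
        window = "N" * 30 + "A" * 12 + "T" + "A" * 24 + "N" * 30
        assert v.verify(read, claimed, window)

    def test_unalignable_read_rejected(self):
        v = RealignmentVerifier()
        assert not v.verify("A" * 40, "C" * 40, "G" * 200)


class TestHqFraction:
    def _site(self, n_hq, n_lq):
        site = make_site(n_hq + n_lq, 0)
        for i, obs in enumerate(site.observations):
            good = i < n_hq
            obs.realignment_confirmed = good
            obs.not_near_end_or_junction = good
        return site

    @pytest.mark.parametrize("n_hq,expect", [(50, True), (49, False), (100, True)])
    def test_half_support_boundary(self, n_hq, expect):
        site = self._site(n_hq, 100 - n_hq)
        assert hq_fraction_filter(_candidate(100, 10), site) is expect

    def test_confirmed_but_near_junction_is_not_hq(self):
        site = self._site(49, 51)
        site.observations[60].realignment_confirmed = True  # still near junction
        assert not hq_fraction_filter(_candidate(100, 10), site)


def test_filters_are_order_independent():
    """Pure predicates: every ordering produces identical verdicts."""
    site = make_site(40, 8)
    cand = _candidate(48, 8, site=site)
    mask = RegionMask.from_intervals([("chr1", 500, 600)])

    def apply_all(order):
        c = _candidate(48, 8, site=site)
        steps = {
            "depth_vaf": lambda: c.record("depth_vaf", depth_vaf_filter(c)),
            "region": lambda: c.record("region", region_mask_filter(c, [mask])),
            "strand": lambda: c.record(
                "strand", allele_bias_filter(c, site, "strand").verdict == "pass"
            ),
        }
        for name in order:
            steps[name]()
        return dict(c.filter_verdicts)

    import itertools

    results = [apply_all(order) for order in itertools.permutations(
        ["depth_vaf", "region", "strand"]
    )]
    assert all(r == results[0] for r in results)
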