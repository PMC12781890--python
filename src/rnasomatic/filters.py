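"""Empirical artifact filters.

Each filter is a pure predicate over (candidate, site, config): verdicts are
recorded on the candidate but never depend on the order in which the filters
run.  Boundary semantics follow strict-less-than throughout: a candidate at
exactly 5% VAF, exactly 5 supporting reads, or exactly 50% high-quality
support passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from intervaltree import IntervalTree
from scipy.stats import hypergeom, mannwhitneyu

# relative tie tolerance for the two-sided Fisher test, the convention shared
# by R's fisher.test and scipy: tables whose probability is within this
# relative margin of the observed table count toward the p-value
_FISHER_TIE_TOL = 1.0 + 1e-7


def fisher_pvalues_for_margins(total: int, row1: int, col1: int) -> tuple[int, np.ndarray]:
    """Two-sided Fisher exact p-values for every table with fixed margins.

    For the 2x2 family with grand total ``total``, first-row sum ``row1``
    and first-column sum ``col1``, returns (k_min, p) where ``p[i]`` is the
    p-value of the table whose top-left cell is ``k_min + i``.  The
    two-sided p sums hypergeometric probabilities of all tables no more
    likely than the observed one; grouping by margins makes an exhaustive
    scan over all small tables cheap.
    """
    k_lo = max(0, col1 - (total - row1))
    k_hi = min(col1, row1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = hypergeom.pmf(ks, total, row1, col1)
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    sorted_pmf = pmf[order]
    idx = np.searchsorted(sorted_pmf, pmf * _FISHER_TIE_TOL, side="right")
    p = np.where(idx > 0, csum[np.minimum(idx, csum.size) - 1], 0.0)
    return int(k_lo), np.minimum(p, 1.0)


def fisher_exact_two_sided(table) -> tuple[float, float]:
    """(odds ratio, two-sided p) for a 2x2 table by direct enumeration."""
    (a, b), (c, d) = table
    total, row1, col1 = a + b + c + d, a + b, a + c
    if total == 0:
        return float("nan"), 1.0
    k_lo, pvals = fisher_pvalues_for_margins(total, row1, col1)
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return odds, float(pvals[a - k_lo])

from .genotyper import Candidate
from .pileup import PileupSite


@dataclass(slots=True)
class BiasTestResult:
    attribute: str
    statistic: float
    p_value: float
    verdict: str  # pass / fail
    testable: bool = True


@dataclass
class RegionMask:
    """Merged half-open (0-based) intervals to exclude, e.g. repeats."""

    source: str
    trees: dict[str, IntervalTree]

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[str, int, int]], source: str = "mask"
    ) -> "RegionMask":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for tree in trees.values():
            tree.merge_overlaps()
        return cls(source=source, trees=trees)

    @classmethod
    def from_bed(cls, path: str, source: str = "repeat_bed") -> "RegionMask":
        intervals = []
        with open(path) as handle:
            for line in handle:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.append((chrom, int(start), int(end)))
        return cls.from_intervals(intervals, source=source)

    def contains(self, chrom: str, pos: int) -> bool:
        """pos is 1-based; intervals are 0-based half-open."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def total_bp(self) -> int:
        return sum(iv.end - iv.begin for t in self.trees.values() for iv in t)


def depth_vaf_filter(
    candidate: Candidate, min_vaf: float = 0.05, min_alt_reads: int = 5
) -> bool:
    """Pass unless VAF or alternate support falls strictly below threshold."""
    return candidate.vaf >= min_vaf and candidate.alt_count >= min_alt_reads


def homopolymer_scan(
    reference: dict[str, str] | Iterable[tuple[str, str]],
    min_run: int = 5,
    pad_bp: int = 1,
) -> RegionMask:
    """Mask all runs of >= ``min_run`` identical bases, padded by ``pad_bp``.

    ``reference`` may be a mapping chrom -> sequence or an iterable of
    (chrom, sequence) pairs (e.g. pyfaidx records coerced to str).
    """
    items = reference.items() if isinstance(reference, dict) else reference
    intervals: list[tuple[str, int, int]] = []
    for chrom, seq in items:
        seq = str(seq).upper()
        n = len(seq)
        i = 0
        while i < n:
            j = i + 1
            while j < n and seq[j] == seq[i]:
                j += 1
            if j - i >= min_run:
                intervals.append((chrom, max(0, i - pad_bp), min(n, j + pad_bp)))
            i = j
    return RegionMask.from_intervals(intervals, source="homopolymer_scan")


def region_mask_filter(candidate: Candidate, masks: Sequence[RegionMask]) -> bool:
    """Pass iff the candidate position lies outside every mask."""
    return not any(mask.contains(candidate.chrom, candidate.pos) for mask in masks)


def _split_by_allele(site: PileupSite, alt: str):
    ref_obs = [o for o in site.observations if o.base == site.ref_base]
    alt_obs = [o for o in site.observations if o.base == alt]
    return ref_obs, alt_obs


def allele_bias_filter(
    candidate: Candidate,
    site: PileupSite,
    attribute: str,
    alpha: float = 0.01,
) -> BiasTestResult:
    """Test ref vs alt observations for bias in one read attribute.

    strand: two-sided Fisher exact test on the 2x2 (allele x orientation)
    table.  mapq / read_position: two-sided Wilcoxon rank-sum
    (Mann-Whitney U; exact for small tie-free samples, otherwise normal
    approximation with tie correction), with read_position taken as the
    distance to the nearer aligned read end.  With no ref or no alt
    observations the test is untestable and passes.
    """
    ref_obs, alt_obs = _split_by_allele(site, candidate.alt_allele)
    if not ref_obs or not alt_obs:
        return BiasTestResult(attribute, float("nan"), 1.0, "pass", testable=False)
    if attribute == "strand":
        table = [
            [sum(o.strand == "+" for o in ref_obs), sum(o.strand == "-" for o in ref_obs)],
            [sum(o.strand == "+" for o in alt_obs), sum(o.strand == "-" for o in alt_obs)],
        ]
        stat, p = fisher_exact_two_sided(table)
    elif attribute in ("mapq", "read_position"):
        attr = "mapq" if attribute == "mapq" else "dist_to_read_end"
        x = [getattr(o, attr) for o in ref_obs]
        y = [getattr(o, attr) for o in alt_obs]
        if len(set(x)) == 1 and set(x) == set(y):
            stat, p = 0.0, 1.0  # all values identical: no bias measurable
        else:
            res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown bias attribute {attribute!r}")
    return BiasTestResult(attribute, float(stat), float(p), "fail" if p < alpha else "pass")


def linkage_filter(
    candidates: Sequence[Candidate],
    min_shared: int = 2,
    window_bp: int = 1000,
) -> dict[tuple, bool]:
    """Flag pairs of nearby candidates in complete linkage on shared pairs.

    For every candidate pair within ``window_bp`` co-covered by at least
    ``min_shared`` read pairs: if the co-covering pairs carrying the
    alternate at one site are exactly those carrying it at the other (and
    that set is non-empty), both candidates fail — the signature of a
    misaligned read population.  Returns candidate.key -> passed.
    """
    verdicts: dict[tuple, bool] = {c.key: True for c in candidates}
    alleles: list[dict[str, bool]] = []
    for cand in candidates:
        if cand.site is None:
            alleles.append({})
            continue
        by_pair: dict[str, bool] = {}
        for obs in cand.site.observations:
            by_pair[obs.pair_id] = obs.base == cand.alt_allele
        alleles.append(by_pair)
    ordered = sorted(range(len(candidates)), key=lambda i: (candidates[i].chrom, candidates[i].pos))
    for ai in range(len(ordered)):
        i = ordered[ai]
        a = candidates[i]
        for bi in range(ai + 1, len(ordered)):
            j = ordered[bi]
            b = candidates[j]
            if b.chrom != a.chrom or b.pos - a.pos > window_bp:
                break
            shared = alleles[i].keys() & alleles[j].keys()
            if len(shared) < min_shared:
                continue
            alt_a = {p for p in shared if alleles[i][p]}
            alt_b = {p for p in shared if alleles[j][p]}
            if alt_a and alt_a == alt_b:
                verdicts[a.key] = False
                verdicts[b.key] = False
    return verdicts


@dataclass
class RealignmentVerifier:
    """Confirm a read's reported locus by independent local realignment.

    The read is scored against the reference it claims to come from (its
    aligned blocks concatenated, i.e. the spliced reference) and against the
    surrounding genomic window with the claimed blocks masked out.  The
    placement is confirmed when the claimed-locus score beats the best
    alternative placement by at least ``min_margin`` and itself reaches
    ``min_score_frac`` of the perfect score.  Any engine honouring this
    contract (e.g. an external-aligner adapter) may substitute.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_margin: float = 5.0
    min_score_frac: float = 0.5

    def __post_init__(self) -> None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        self._aligner = aligner

    def verify(
        self,
        read_bases: str,
        claimed_reference: str,
        window_masked: str,
    ) -> bool:
        """True iff the claimed locus is the unique best placement."""
        if not read_bases:
            return False
        score_claim = self._aligner.score(claimed_reference, read_bases)
        if score_claim < self.min_score_frac * self.match * len(read_bases):
            return False
        if not window_masked.strip("N"):
            return True
        score_alt = self._aligner.score(window_masked, read_bases)
        return score_claim - score_alt >= self.min_margin


def realignment_verify(
    read,
    reference,
    verifier: RealignmentVerifier | None = None,
    window_factor: int = 2,
) -> bool:
    """Verify one :class:`~rnasomatic.pileup.ReadRecord` against the genome.

    The alternative-placement window spans the aligned locus plus
    ``window_factor`` read lengths on each side, with the claimed blocks
    masked to N so tandem duplications compete as alternative placements.
    """
    verifier = verifier or RealignmentVerifier()
    chrom_seq = str(reference[read.chrom]) if not isinstance(reference, dict) else reference[read.chrom]
    chrom_seq = chrom_seq.upper()
    read_len = len(read.bases)
    claimed = "".join(chrom_seq[s - 1 : e] for s, e in read.aligned_blocks)
    w_start = max(0, read.start - 1 - window_factor * read_len)
    w_end = min(len(chrom_seq), read.end + window_factor * read_len)
    window = list(chrom_seq[w_start:w_end])
    for s, e in read.aligned_blocks:
        for p in range(max(s - 1, w_start), min(e, w_end)):
            window[p - w_start] = "N"
    return verifier.verify(read.bases, claimed, "".join(window))


def hq_fraction_filter(
    candidate: Candidate, site: PileupSite, min_fraction: float = 0.5
) -> bool:
    """Pass unless fewer than ``min_fraction`` of covering reads are high quality.

    A high-quality read is one whose alignment was re-confirmed by the
    independent realigner and whose base is not near a read end or splice
    junction; exactly 50% high-quality passes (strict "fewer than").
    """
    depth = site.depth
    if depth == 0:
        return True
    hq = sum(
        1
        for o in site.observations
        if o.realignment_confirmed and o.not_near_end_or_junction
    )
    return hq / depth >= min_fraction
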