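"""Evaluation and characterisation: powered regions, sensitivity/precision,
burden per megabase, 96-channel trinucleotide spectra, cosine similarity.

Sensitivity is computed against truth restricted to powered regions
(territory with calling-grade coverage); precision is computed over all
calls.  The asymmetry is deliberate: coverage limits what is recoverable,
but every emitted call is accountable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def spectrum_channels() -> list[str]:
    """The canonical 96 pyrimidine-centric channels, e.g. ``A[C>T]G``."""
    channels = []
    for sub in PYRIMIDINE_SUBS:
        ref = sub[0]
        for five in "ACGT":
            for three in "ACGT":
                channels.append(f"{five}[{sub}]{three}")
    return channels


CHANNELS_96 = spectrum_channels()
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}


@dataclass
class PoweredRegion:
    """Maximal intervals (1-based inclusive) with calling-grade depth."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def total_bp(self) -> int:
        return sum(e - s + 1 for ivs in self.intervals.values() for s, e in ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        for s, e in self.intervals.get(chrom, ()):
            if s <= pos <= e:
                return True
        return False


def powered_regions(
    depth_track: Iterable[tuple[str, int, int]] | Mapping[str, Sequence[int]],
    min_depth: int = 10,
) -> PoweredRegion:
    """Collapse a per-position depth track into powered intervals.

    Accepts either (chrom, pos, depth) triples (pos 1-based) or a mapping
    chrom -> dense depth array starting at position 1.
    """
    region = PoweredRegion()
    if isinstance(depth_track, Mapping):
        triples: list[tuple[str, int, int]] = []
        for chrom, depths in depth_track.items():
            triples.extend(
                (chrom, i + 1, int(d)) for i, d in enumerate(depths)
            )
    else:
        triples = list(depth_track)
    triples.sort(key=lambda t: (t[0], t[1]))
    current: tuple[str, int, int] | None = None  # chrom, start, end
    for chrom, pos, depth in triples:
        if depth < min_depth:
            continue
        if current is not None and chrom == current[0] and pos == current[2] + 1:
            current = (chrom, current[1], pos)
        else:
            if current is not None:
                region.intervals.setdefault(current[0], []).append(current[1:])
            current = (chrom, pos, pos)
    if current is not None:
        region.intervals.setdefault(current[0], []).append(current[1:])
    return region


def powered_from_positions(positions: Iterable[tuple[str, int]]) -> PoweredRegion:
    """Powered intervals from the set of positions that passed the depth gate."""
    return powered_regions(((c, p, 10**9) for c, p in positions), min_depth=1)


def evaluate_calls(
    calls: Iterable[tuple],
    truth: Iterable[tuple],
    powered: PoweredRegion | None = None,
) -> tuple[float, float]:
    """(sensitivity, precision) matching on (chrom, pos, ref, alt).

    Sensitivity uses powered truth as denominator (all truth when no
    powered region is given); precision uses all calls.  Undefined ratios
    (empty denominators) are returned as NaN, never 0.
    """
    call_set = set(calls)
    truth_set = set(truth)
    if powered is not None:
        truth_powered = {t for t in truth_set if powered.contains(t[0], t[1])}
    else:
        truth_powered = truth_set
    sensitivity = (
        len(call_set & truth_powered) / len(truth_powered)
        if truth_powered
        else float("nan")
    )
    precision = (
        len(call_set & truth_set) / len(call_set) if call_set else float("nan")
    )
    return sensitivity, precision


def burden_per_mb(n_variants: int, powered: PoweredRegion) -> float:
    """Somatic burden normalised to powered megabases; NaN on empty territory."""
    total = powered.total_bp
    if total == 0:
        return float("nan")
    return n_variants / (total / 1e6)


@dataclass
class Spectrum96:
    counts: np.ndarray  # shape (96,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self, weights: np.ndarray | None = None) -> np.ndarray:
        """Proportions, optionally divided by per-channel opportunity weights
        (e.g. trinucleotide frequencies of the powered territory) and
        renormalised."""
        v = self.counts.copy()
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                v = np.where(weights > 0, v / weights, 0.0)
        s = v.sum()
        return v / s if s > 0 else v


def trinucleotide_spectrum(
    calls: Iterable[tuple],
    reference: Mapping[str, str],
    weights: np.ndarray | None = None,
) -> Spectrum96:
    """Assign each (chrom, pos, ref, alt) call to its 96-channel bin.

    Purine-reference substitutions are collapsed to the pyrimidine strand
    with reverse-complemented context.  Calls at contig edges (no flanking
    context) are skipped.
    """
    counts = np.zeros(96)
    for chrom, pos, ref, alt in calls:
        seq = reference[chrom]
        seq = seq if isinstance(seq, str) else str(seq)
        if pos - 2 < 0 or pos >= len(seq):
            continue
        tri = seq[pos - 2 : pos + 1].upper()
        if any(b not in _COMPLEMENT for b in tri) or tri[1] != ref:
            continue
        if ref in "AG":
            tri = _revcomp(tri)
            ref = _COMPLEMENT[ref]
            alt = _COMPLEMENT[alt]
        channel = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
        counts[_CHANNEL_INDEX[channel]] += 1
    return Spectrum96(counts)


def trinucleotide_weights(reference: Mapping[str, str], powered: PoweredRegion) -> np.ndarray:
    """Per-channel trinucleotide opportunity counts in powered territory."""
    weights = np.zeros(96)
    for chrom, intervals in powered.intervals.items():
        seq = reference[chrom]
        seq = seq if isinstance(seq, str) else str(seq)
        for s, e in intervals:
            for pos in range(max(s, 2), min(e, len(seq) - 1) + 1):
                tri = seq[pos - 2 : pos + 1].upper()
                if any(b not in _COMPLEMENT for b in tri):
                    continue
                center = tri[1]
                ctx = tri if center in "CT" else _revcomp(tri)
                for alt in "ACGT":
                    if alt == ctx[1]:
                        continue
                    weights[_CHANNEL_INDEX[f"{ctx[0]}[{ctx[1]}>{alt}]{ctx[2]}"]] += 1
    return weights


def cosine_similarity(s1: np.ndarray | Spectrum96, s2: np.ndarray | Spectrum96) -> float:
    """Inner-product cosine over the 96 channels; NaN for a zero vector."""
    v1 = s1.counts if isinstance(s1, Spectrum96) else np.asarray(s1, dtype=float)
    v2 = s2.counts if isinstance(s2, Spectrum96) else np.asarray(s2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    return float(np.dot(v1, v2) / (n1 * n2))


def proportion_ztest(
    count1: int, total1: int, count2: int, total2: int
) -> tuple[float, float, float]:
    """Two-sample Z-test of proportions plus odds ratio.

    Returns (odds_ratio, z, two_sided_p); used for group burden comparisons
    (e.g. case vs control variant density over powered territory).
    """
    from scipy.stats import norm

    p1, p2 = count1 / total1, count2 / total2
    pooled = (count1 + count2) / (total1 + total2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / total1 + 1 / total2))
    z = (p1 - p2) / se if se > 0 else float("nan")
    p_value = 2 * norm.sf(abs(z)) if not math.isnan(z) else float("nan")
    if count2 == 0 or count1 == total1 or count2 == total2 or count1 == 0:
        odds = float("nan")
    else:
        odds = (p1 / (1 - p1)) / (p2 / (1 - p2))
    return odds, z, p_value
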