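"""Bayesian genotyper over pileup sites.

At each site the model compares four genotype states G for the most
frequent non-reference allele: homozygous reference, germline heterozygous,
homozygous alternate, and somatic mosaic with an unknown cell fraction
f in (0, 1).  The per-base likelihood uses the Phred error probability
eps = 10^(-q/10):

    P(o | allele, q) = 1 - eps   if o == allele
                       eps / 3   otherwise

and a read drawn from a site with alternate fraction f contributes

    (1 - f) * P(o | ref, q) + f * P(o | alt, q).

The germline states are the fixed-fraction cases f = 0, 1/2, 1; the mosaic
state marginalises f over a prior (uniform by default) with Gauss-Legendre
quadrature.  Genotype priors follow Hardy-Weinberg on the population
alternate-allele frequency p_alt, scaled by (1 - p_m), with p_m reserved
for the mosaic state.  All likelihood arithmetic is in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from scipy.special import logsumexp

from .pileup import PileupSite

GENOTYPES = ("hom_ref", "het", "hom_alt", "mosaic")
_BASES = ("A", "C", "G", "T")


@dataclass
class GenotypeModel:
    """Priors and quadrature settings for the four-state genotyper."""

    p_m: float = 1e-7
    default_p_alt: float = 1e-4
    allele_fraction_prior: tuple[float, float] = (1.0, 1.0)  # Beta(a, b)
    quadrature_points: int = 512

    def __post_init__(self) -> None:
        for name in ("p_m", "default_p_alt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.quadrature_points < 64:
            raise ValueError("quadrature_points must be >= 64")

    _nodes_cache: dict = field(default_factory=dict, repr=False)

    def quadrature(self) -> tuple[np.ndarray, np.ndarray]:
        """Gauss-Legendre nodes on (0, 1) and log-weights including the prior.

        Cached per model; exact for polynomial integrands up to degree
        2K - 1, which covers every finite-depth likelihood in the
        error-free limit.
        """
        key = (self.quadrature_points, self.allele_fraction_prior)
        if key not in self._nodes_cache:
            x, w = np.polynomial.legendre.leggauss(self.quadrature_points)
            f = 0.5 * (x + 1.0)
            logw = np.log(0.5 * w)
            a, b = self.allele_fraction_prior
            if (a, b) != (1.0, 1.0):
                from scipy.stats import beta

                logw = logw + beta.logpdf(f, a, b)
            self._nodes_cache[key] = (f, logw)
        return self._nodes_cache[key]


@dataclass(slots=True)
class GenotypePosterior:
    probs: dict[str, float]
    alt_allele: str
    log_likelihoods: dict[str, float]


@dataclass(slots=True)
class Candidate:
    """A nominated variant site accumulating filter verdicts."""

    chrom: str
    pos: int
    ref_base: str
    alt_allele: str
    depth: int
    alt_count: int
    vaf: float
    posterior: GenotypePosterior
    filter_verdicts: dict[str, str] = field(default_factory=dict)
    gene_context: list = field(default_factory=list)
    site: PileupSite | None = None
    germline_status: str | None = None

    def record(self, name: str, passed: bool) -> None:
        self.filter_verdicts[name] = "pass" if passed else "fail"

    @property
    def passes_all(self) -> bool:
        return all(v == "pass" for v in self.filter_verdicts.values())

    @property
    def first_failed(self) -> str | None:
        for name, verdict in self.filter_verdicts.items():
            if verdict == "fail":
                return name
        return None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_allele)


def genotype_priors(model: GenotypeModel, p_alt: float | None = None) -> dict[str, float]:
    """Hardy-Weinberg genotype priors with a reserved mosaic mass p_m."""
    pa = model.default_p_alt if p_alt is None else p_alt
    if not 0.0 <= pa <= 1.0:
        raise ValueError(f"p_alt={pa} must be a probability in [0, 1]")
    pm = model.p_m
    return {
        "hom_ref": (1.0 - pa) ** 2 * (1.0 - pm),
        "het": 2.0 * pa * (1.0 - pa) * (1.0 - pm),
        "hom_alt": pa**2 * (1.0 - pm),
        "mosaic": pm,
    }


def _site_arrays(site: PileupSite, alt: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse observations to (eps, n_ref, n_alt_or_other) per unique quality.

    Returns arrays (eps, ref_counts, alt_counts, other_counts) grouped by
    unique Phred quality, which makes the fraction-grid likelihood a small
    matrix product regardless of depth.
    """
    quals = np.fromiter((o.qual for o in site.observations), dtype=np.int64)
    ref_b = site.ref_base
    cls = np.fromiter(
        (
            0 if o.base == ref_b else (1 if o.base == alt else 2)
            for o in site.observations
        ),
        dtype=np.int64,
    )
    uq = np.unique(quals)
    counts = np.zeros((uq.size, 3), dtype=np.float64)
    idx = np.searchsorted(uq, quals)
    np.add.at(counts, (idx, cls), 1.0)
    eps = 10.0 ** (-uq / 10.0)
    return eps, counts


def _loglik_grid(site: PileupSite, alt: str, f: np.ndarray) -> np.ndarray:
    """log-likelihood of the data at each allele fraction in ``f``."""
    if not site.observations:
        return np.zeros_like(f)
    eps, counts = _site_arrays(site, alt)
    f = np.atleast_1d(f)[None, :]  # (1, F)
    eps_c = eps[:, None]
    p_ref = (1.0 - f) * (1.0 - eps_c) + f * (eps_c / 3.0)
    p_alt = (1.0 - f) * (eps_c / 3.0) + f * (1.0 - eps_c)
    p_other = np.full_like(p_ref, 1.0) * (eps_c / 3.0)
    with np.errstate(divide="ignore"):
        ll = (
            counts[:, 0:1] * np.log(p_ref)
            + counts[:, 1:2] * np.log(p_alt)
            + counts[:, 2:3] * np.log(p_other)
        )
    return ll.sum(axis=0)


def fixed_fraction_likelihood(site: PileupSite, alt: str, f: float) -> float:
    """Log-likelihood of the site data at a fixed alternate fraction f.

    f = 0, 0.5 and 1 give the three germline states.  An empty site returns
    0 (the vacuous product).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    return float(_loglik_grid(site, alt, np.array([f]))[0])


def mosaic_marginal_likelihood(site: PileupSite, alt: str, model: GenotypeModel) -> float:
    """Log of the likelihood marginalised over the mosaic fraction prior."""
    if not site.observations:
        return 0.0
    f, logw = model.quadrature()
    return float(logsumexp(_loglik_grid(site, alt, f) + logw))


def pick_alt_allele(site: PileupSite) -> tuple[str, int, int]:
    """Most frequent non-reference base (ties broken lexicographically).

    Returns (alt, alt_count, second_alt_count); N calls never count.
    """
    counts = site.base_counts()
    alts = sorted(
        ((b, c) for b, c in counts.items() if b != site.ref_base and b in _BASES),
        key=lambda bc: (-bc[1], bc[0]),
    )
    if not alts:
        # no non-reference evidence; report a deterministic placeholder
        alt = next(b for b in _BASES if b != site.ref_base)
        return alt, 0, 0
    second = alts[1][1] if len(alts) > 1 else 0
    return alts[0][0], alts[0][1], second


def compute_posteriors(
    site: PileupSite,
    model: GenotypeModel,
    snp_db=None,
) -> GenotypePosterior:
    """Posterior over the four genotype states for the site's top alternate.

    ``snp_db`` maps (chrom, pos, ref, alt) to a population allele frequency
    (see :class:`rnasomatic.germline.SnpFrequencyDb`); sites absent from it
    fall back to the model's ``default_p_alt``.
    """
    alt, _, _ = pick_alt_allele(site)
    p_alt = None
    if snp_db is not None:
        p_alt = snp_db.allele_frequency(site.chrom, site.pos, site.ref_base, alt)
    priors = genotype_priors(model, p_alt)
    ll = {
        "hom_ref": fixed_fraction_likelihood(site, alt, 0.0),
        "het": fixed_fraction_likelihood(site, alt, 0.5),
        "hom_alt": fixed_fraction_likelihood(site, alt, 1.0),
        "mosaic": mosaic_marginal_likelihood(site, alt, model),
    }
    log_post = np.array(
        [np.log(priors[g]) if priors[g] > 0 else -np.inf for g in GENOTYPES]
    ) + np.array([ll[g] for g in GENOTYPES])
    log_post -= logsumexp(log_post)
    probs = dict(zip(GENOTYPES, np.exp(log_post)))
    return GenotypePosterior(probs=probs, alt_allele=alt, log_likelihoods=ll)


def site_to_candidate(
    site: PileupSite,
    posterior: GenotypePosterior,
    keep_site: bool = True,
) -> Candidate:
    counts = site.base_counts()
    alt_count = counts.get(posterior.alt_allele, 0)
    depth = site.depth
    return Candidate(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=site.ref_base,
        alt_allele=posterior.alt_allele,
        depth=depth,
        alt_count=alt_count,
        vaf=alt_count / depth if depth else 0.0,
        posterior=posterior,
        site=site if keep_site else None,
    )


def select_candidates(
    posterior_stream: Iterable[tuple[PileupSite, GenotypePosterior]],
    min_candidate_posterior: float = 0.05,
) -> Iterator[Candidate]:
    """Nominate sites whose het + mosaic posterior clears the threshold.

    A site with no alternate-supporting base is never nominated, whatever
    its posterior under pathological priors.
    """
    for site, post in posterior_stream:
        mass = post.probs["het"] + post.probs["mosaic"]
        if mass < min_candidate_posterior:
            continue
        cand = site_to_candidate(site, post)
        if cand.alt_count < 1:
            continue
        yield cand
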