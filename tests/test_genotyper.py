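"""Priors, likelihoods, quadrature marginal, and candidate nomination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from rnasomatic.genotyper import (
    GENOTYPES,
    GenotypeModel,
    compute_posteriors,
    fixed_fraction_likelihood,
    genotype_priors,
    mosaic_marginal_likelihood,
    pick_alt_allele,
    select_candidates,
)
from rnasomatic.pileup import PileupSite

from conftest import make_site


@pytest.fixture()
def model():
    return GenotypeModel()


class TestPriors:
    def test_degenerate_absent_allele(self):
        pri = genotype_priors(GenotypeModel(p_m=1e-7), p_alt=0.0)
        assert pri["hom_ref"] == pytest.approx(1 - 1e-7)
        assert pri["het"] == 0 and pri["hom_alt"] == 0
        assert pri["mosaic"] == pytest.approx(1e-7)

    def test_symmetric_hardy_weinberg(self):
        pri = genotype_priors(GenotypeModel(p_m=0.0), p_alt=0.5)
        assert (pri["hom_ref"], pri["het"], pri["hom_alt"], pri["mosaic"]) == (
            0.25, 0.5, 0.25, 0.0,
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        p_alt=st.floats(0, 1, allow_nan=False),
        p_m=st.floats(0, 1e-3, allow_nan=False),
    )
    def test_priors_sum_to_one(self, p_alt, p_m):
        pri = genotype_priors(GenotypeModel(p_m=p_m), p_alt=p_alt)
        assert sum(pri.values()) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            genotype_priors(GenotypeModel(), p_alt=1.5)


class TestLikelihoods:
    def test_reference_only_product(self, model):
        site = make_site(10, 0, qual=30)
        assert fixed_fraction_likelihood(site, "G", 0.0) == pytest.approx(
            10 * math.log(1 - 1e-3)
        )

    def test_balanced_error_free_half(self, model):
        site = make_site(1, 1, qual=1000)
        assert fixed_fraction_likelihood(site, "G", 0.5) == pytest.approx(
            math.log(0.25)
        )

    def test_ref_alt_swap_symmetry(self, model):
        a = fixed_fraction_likelihood(make_site(7, 3, qual=1000), "G", 0.2)
        b = fixed_fraction_likelihood(make_site(3, 7, qual=1000), "G", 0.8)
        assert a == pytest.approx(b, rel=1e-12)

    def test_empty_site_is_vacuous(self, model):
        site = PileupSite("chr1", 5, "A", [])
        assert fixed_fraction_likelihood(site, "G", 0.3) == 0.0
        assert mosaic_marginal_likelihood(site, "G", model) == 0.0

    def test_marginal_closed_form_single_ref(self, model):
        # integral of (1 - f) over the uniform prior is exactly 1/2
        got = mosaic_marginal_likelihood(make_site(1, 0, qual=1000), "G", model)
        assert got == pytest.approx(math.log(0.5), abs=1e-6)

    def test_marginal_closed_form_beta_2_2(self, model):
        # integral of f(1 - f) is the Beta(2,2) normaliser 1/6
        got = mosaic_marginal_likelihood(make_site(1, 1, qual=1000), "G", model)
        assert got == pytest.approx(math.log(1 / 6), abs=1e-6)


def _oracle_posterior(n_ref, n_alt, qual, p_alt, p_m, grid=100_001):
    """Dense-grid trapezoid integration, independent of the package path."""
    eps = 10.0 ** (-qual / 10.0)
    f = np.linspace(0.0, 1.0, grid)

    def loglik(frac):
        p_r = (1 - frac) * (1 - eps) + frac * eps / 3
        p_a = (1 - frac) * eps / 3 + frac * (1 - eps)
        return n_ref * np.log(p_r) + n_alt * np.log(p_a)

    w = np.full(grid, 1.0 / (grid - 1))
    w[0] /= 2
    w[-1] /= 2
    marg = logsumexp(loglik(f) + np.log(w))
    pri = {
        "hom_ref": (1 - p_alt) ** 2 * (1 - p_m),
        "het": 2 * p_alt * (1 - p_alt) * (1 - p_m),
        "hom_alt": p_alt**2 * (1 - p_m),
        "mosaic": p_m,
    }
    ll = {
        "hom_ref": float(loglik(0.0)),
        "het": float(loglik(0.5)),
        "hom_alt": float(loglik(1.0)),
        "mosaic": float(marg),
    }
    lp = np.array([np.log(pri[g]) + ll[g] for g in GENOTYPES])
    lp -= logsumexp(lp)
    return dict(zip(GENOTYPES, np.exp(lp)))


class TestPosteriors:
    def test_reference_dominated(self, model):
        post = compute_posteriors(make_site(200, 0, qual=30), model)
        assert post.probs["hom_ref"] > 0.999

    def test_balanced_deep_site_is_het(self):
        model = GenotypeModel(default_p_alt=0.3)
        post = compute_posteriors(make_site(50, 50, qual=30), model)
        assert max(post.probs, key=post.probs.get) == "het"

    def test_low_fraction_site_matches_grid_oracle(self, model):
        post = compute_posteriors(make_site(17, 3, qual=30), model)
        oracle = _oracle_posterior(17, 3, 30, model.default_p_alt, model.p_m)
        for g in GENOTYPES:
            assert post.probs[g] == pytest.approx(oracle[g], rel=1e-6, abs=1e-12)

    def test_posterior_normalisation(self, model):
        for n_alt in (0, 1, 5, 20):
            post = compute_posteriors(make_site(40 - n_alt, n_alt), model)
            assert sum(post.probs.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(p >= 0 for p in post.probs.values())

    def test_hom_ref_posterior_monotone_in_alt_count(self, model):
        values = [
            compute_posteriors(make_site(30 - a, a, qual=30), model).probs["hom_ref"]
            for a in range(0, 10)
        ]
        assert all(x >= y - 1e-12 for x, y in zip(values, values[1:]))

    def test_alt_allele_tie_breaks_lexicographically(self):
        site = make_site(20, 0, ref="A")
        site.observations[0].base = "T"
        site.observations[1].base = "C"
        assert pick_alt_allele(site)[0] == "C"


class TestSelection:
    def test_threshold_suppresses_weak_sites(self, model):
        site = make_site(199, 1, qual=30)
        post = compute_posteriors(site, model)
        assert post.probs["het"] + post.probs["mosaic"] < 0.05
        assert not list(select_candidates([(site, post)], 0.05))

    def test_confident_het_is_nominated(self, model):
        site = make_site(50, 50, qual=30)
        post = compute_posteriors(site, model)
        (cand,) = select_candidates([(site, post)], 0.05)
        assert cand.alt_count == 50 and cand.vaf == pytest.approx(0.5)
        assert cand.filter_verdicts == {}

    def test_no_alt_support_never_nominated(self, model):
        site = make_site(20, 0, qual=30)
        post = compute_posteriors(site, model)
        post.probs = {"hom_ref": 0.9, "het": 0.06, "hom_alt": 0.0, "mosaic": 0.04}
        assert not list(select_candidates([(site, post)], 0.05))
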