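"""Unit and property tests of the Bayesian observation/genotype model."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylsnp import (
    GENOTYPES,
    ModelParams,
    PileupLocus,
    PriorParams,
    ReadObservation,
    allele_observation_likelihood,
    genotype_likelihood,
    genotype_priors,
    locus_posterior,
    make_genotype,
    methylation_from_call,
)
from methylsnp.model import TRANSITION

from conftest import make_locus, make_obs


def enumeration_oracle(obs_base, strand, allele, beta, alpha, gamma, eps):
    """Exhaustive enumeration over the latent (methylated, converted,
    error target) states of the two-stage bisulfite + error model.

    Deliberately independent of the implementation: it walks every latent
    combination and sums path probabilities.
    """
    affected = (allele == "C" and strand == "forward") or (
        allele == "G" and strand == "reverse"
    )
    if not affected:
        template_states = [(allele, 1.0)]
    else:
        stays, converts = ("C", "T") if allele == "C" else ("G", "A")
        template_states = []
        for meth, p_meth in ((True, beta), (False, 1.0 - beta)):
            p_conv = gamma if meth else 1.0 - alpha
            template_states.append((converts, p_meth * p_conv))
            template_states.append((stays, p_meth * (1.0 - p_conv)))
    total = 0.0
    for template, p_template in template_states:
        for target in "ACGT":
            p_err = (1.0 - eps) if target == template else eps / 3.0
            if target == obs_base:
                total += p_template * p_err
    return total


class TestGenotypePriors:
    def test_reference_homozygote_mass_novel(self):
        pri = genotype_priors("A", None, PriorParams(theta_novel=1e-3))
        assert pri[("A", "A")] == pytest.approx(0.999)

    def test_normalization(self):
        for ref in "ACGT":
            pri = genotype_priors(ref)
            assert sum(pri.values()) == pytest.approx(1.0)

    def test_known_site_theta_and_transition_weighting(self):
        class Known:
            alt_frequencies = {}

        pri = genotype_priors("A", Known(), PriorParams(theta_known=0.1))
        assert pri[("A", "A")] == pytest.approx(0.9)
        # A->G is the transition: favored over transversions
        assert pri[("A", "G")] > pri[("A", "C")]

    def test_allele_frequencies_absorb_variant_mass(self):
        class Known:
            alt_frequencies = {"T": 0.3}

        pri = genotype_priors("A", Known())
        # the listed alt now out-weighs the unlisted transition allele
        assert pri[("A", "T")] > pri[("A", "G")]

    def test_n_reference_uniform(self):
        pri = genotype_priors("N")
        assert all(v == pytest.approx(0.1) for v in pri.values())


class TestAlleleObservationLikelihood:
    def test_unmethylated_perfect_conversion(self):
        obs = make_obs("T", eps=1e-12)
        p = allele_observation_likelihood(
            obs, "C", 0.0, ModelParams(alpha=0.0, gamma=0.0)
        )
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_methylated_protected(self):
        obs = make_obs("C", eps=1e-12)
        p = allele_observation_likelihood(
            obs, "C", 1.0, ModelParams(alpha=0.0, gamma=0.0)
        )
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_half_methylated_printed_value(self):
        obs = make_obs("C", eps=0.01)
        p = allele_observation_likelihood(
            obs, "C", 0.5, ModelParams(alpha=0.0, gamma=0.0)
        )
        assert p == pytest.approx(0.5 * 0.99 + 0.5 * 0.01 / 3, abs=1e-12)

    def test_opposite_strand_plain_error_model(self):
        obs = make_obs("C", eps=0.02, strand="reverse")
        assert allele_observation_likelihood(obs, "C", 0.5) == pytest.approx(0.98)

    def test_at_allele_error_split(self):
        obs = make_obs("A", eps=0.03)
        assert allele_observation_likelihood(obs, "T", 0.5) == pytest.approx(0.01)

    @pytest.mark.parametrize("allele", ["C", "G"])
    @pytest.mark.parametrize("strand", ["forward", "reverse"])
    def test_enumeration_oracle_grid(self, allele, strand):
        """Implementation == exhaustive latent-state enumeration on a
        parameter grid, to 1e-12."""
        grid = itertools.product(
            [0.0, 0.25, 0.5, 1.0],  # beta
            [0.0, 0.0025, 0.05],  # alpha
            [0.0, 0.01],  # gamma
            [1e-4, 0.01, 0.2],  # eps
        )
        params_list = list(grid)
        assert len(params_list) >= 36
        for beta, alpha, gamma, eps in params_list:
            mp = ModelParams(alpha=alpha, gamma=gamma)
            for base in "ACGT":
                obs = make_obs(base, eps=eps, strand=strand)
                got = allele_observation_likelihood(obs, allele, beta, mp)
                want = enumeration_oracle(base, strand, allele, beta, alpha, gamma, eps)
                assert got == pytest.approx(want, abs=1e-12)

    @given(
        beta=st.floats(0, 1), alpha=st.floats(0, 1), gamma=st.floats(0, 1),
        eps=st.floats(1e-6, 1.0),
        allele=st.sampled_from("ACGT"),
        strand=st.sampled_from(["forward", "reverse"]),
    )
    @settings(max_examples=200, deadline=None)
    def test_normalizes_over_observed_bases(self, beta, alpha, gamma, eps, allele, strand):
        mp = ModelParams(alpha=alpha, gamma=gamma)
        total = sum(
            allele_observation_likelihood(make_obs(b, eps=eps, strand=strand), allele, beta, mp)
            for b in "ACGT"
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_limit_matches_plain_error_model(self):
        """alpha=gamma=0, beta=1: the bisulfite-strand C model collapses
        exactly onto the plain error model."""
        mp = ModelParams(alpha=0.0, gamma=0.0)
        for eps in (1e-4, 0.01, 0.3):
            for base in "ACGT":
                obs = make_obs(base, eps=eps, strand="forward")
                bis = allele_observation_likelihood(obs, "C", 1.0, mp)
                plain = (1.0 - eps) if base == "C" else eps / 3.0
                assert bis == plain

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            allele_observation_likelihood(make_obs("C"), "C", 1.5)


class TestGenotypeLikelihood:
    def test_empty_pileup_is_unit_likelihood(self):
        locus = make_locus("A")
        for g in GENOTYPES:
            assert genotype_likelihood(locus, g, 0.5, log=False) == 1.0

    def test_homozygous_collapses_to_single_allele(self):
        locus = make_locus("A", bases_fwd="AAGA", bases_rev="AA")
        mp = ModelParams()
        ll = genotype_likelihood(locus, ("A", "A"), 0.5, mp)
        direct = sum(
            math.log(allele_observation_likelihood(o, "A", 0.5, mp))
            for o in locus.observations
        )
        assert ll == pytest.approx(direct, abs=1e-12)

    def test_brute_force_product_oracle(self):
        """5-read pileup likelihood equals an independently coded
        term-by-term product for every genotype."""
        locus = make_locus("C", bases_fwd="CTC", bases_rev="GG", eps=0.01)
        mp = ModelParams()
        beta = 0.3
        for g in GENOTYPES:
            want = 1.0
            for o in locus.observations:
                pa = allele_observation_likelihood(o, g[0], beta, mp)
                pb = allele_observation_likelihood(o, g[1], beta, mp)
                want *= 0.5 * pa + 0.5 * pb
            got = genotype_likelihood(locus, g, beta, mp, log=False)
            assert got == pytest.approx(want, rel=1e-12)


class TestLocusPosterior:
    def test_empty_pileup_returns_prior(self):
        locus = make_locus("A")
        priors = genotype_priors("A")
        call = locus_posterior(locus, priors, 0.5)
        for g in GENOTYPES:
            assert call.posterior[g] == pytest.approx(priors[g], rel=1e-9)
        ordered = sorted(priors.items(), key=lambda kv: -kv[1])
        assert call.score == pytest.approx(
            10 * math.log10(ordered[0][1] / ordered[1][1])
        )

    def test_het_ct_pileup_recovered_by_brute_force(self):
        """Synthetic C/T het: 5 converted C-strand reads plus a reverse
        strand split between the two alleles (read-space 3 G / 2 A =
        forward-normalized 3 C / 2 T); best genotype must be C/T and must
        agree with an independent brute-force posterior enumeration."""
        locus = make_locus("C", bases_fwd="TTTTT", bases_rev="CCCTT", eps=0.001)
        priors = genotype_priors("C")
        mp = ModelParams()
        beta = 0.5
        call = locus_posterior(locus, priors, beta, mp)
        # independent enumeration over all 10 genotypes
        posts = {}
        for g in GENOTYPES:
            like = 1.0
            for o in locus.observations:
                pa = allele_observation_likelihood(o, g[0], beta, mp)
                pb = allele_observation_likelihood(o, g[1], beta, mp)
                like *= 0.5 * pa + 0.5 * pb
            posts[g] = priors[g] * like
        z = sum(posts.values())
        best_oracle = max(posts, key=lambda g: posts[g])
        assert call.best == best_oracle == ("C", "T")
        for g in GENOTYPES:
            assert call.posterior[g] == pytest.approx(posts[g] / z, rel=1e-9)

    @given(
        ref=st.sampled_from("ACGT"),
        n_fwd=st.integers(0, 12),
        n_rev=st.integers(0, 12),
        seed=st.integers(0, 10_000),
        beta=st.floats(0, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_posterior_normalization_property(self, ref, n_fwd, n_rev, seed, beta):
        rng = np.random.default_rng(seed)
        bases_f = "".join(rng.choice(list("ACGT"), n_fwd))
        bases_r = "".join(rng.choice(list("ACGT"), n_rev))
        eps = float(rng.uniform(1e-4, 0.3))
        locus = make_locus(ref, bases_f, bases_r, eps=eps)
        call = locus_posterior(locus, genotype_priors(ref), beta)
        assert sum(call.posterior.values()) == pytest.approx(1.0, abs=1e-9)
        assert call.score >= 0.0

    def test_score_monotone_in_concordant_reads(self):
        """Adding a read matching the best genotype never lowers the
        score."""
        priors = genotype_priors("A")
        prev = None
        for n in range(1, 12):
            locus = make_locus("A", bases_fwd="A" * n, eps=0.01)
            call = locus_posterior(locus, priors, 0.5)
            assert call.best == ("A", "A")
            if prev is not None:
                assert call.score >= prev - 1e-9
            prev = call.score

    def test_tie_scores_zero(self):
        locus = make_locus("A")
        uniform = {g: 0.1 for g in GENOTYPES}
        call = locus_posterior(locus, uniform, 0.5)
        assert call.score == 0.0
        # deterministic canonical tie-break: first two genotypes in order
        assert call.best == GENOTYPES[0]
        assert call.next_best == GENOTYPES[1]


class TestMethylationFromCall:
    def test_fraction_from_c_strand_counts(self):
        # reverse-template reads at a C site show forward-space C
        locus = make_locus("C", bases_fwd="CCCT", bases_rev="CC")
        call = locus_posterior(locus, genotype_priors("C"), 0.75)
        assert call.best == ("C", "C")
        assert call.methylation_fraction == pytest.approx(0.75)
        assert (call.c_reads, call.t_reads) == (3, 1)

    def test_no_informative_reads_flagged_undefined(self):
        locus = make_locus("C", bases_rev="CCCC")
        call = locus_posterior(locus, genotype_priors("C"), 0.5)
        assert call.best == ("C", "C")
        assert call.methylation_fraction is None

    def test_homozygous_t_emits_nothing(self):
        locus = make_locus("T", bases_fwd="TTTT")
        call = locus_posterior(locus, genotype_priors("T"), 0.5)
        frac, c, t, strand = methylation_from_call(call, locus)
        assert frac is None and strand is None

    def test_ct_het_not_measurable(self):
        locus = make_locus("C", bases_fwd="TTTT", bases_rev="CCTT")
        call = locus_posterior(locus, genotype_priors("C"), 0.5)
        assert call.best == ("C", "T")
        assert call.methylation_fraction is None

    def test_reverse_strand_cytosine_uses_g_a_mirror(self):
        locus = make_locus("G", bases_fwd="GGGG", bases_rev="GGGA")
        call = locus_posterior(locus, genotype_priors("G"), 0.75)
        assert call.best == ("G", "G")
        assert call.methylation_strand == "-"
        assert call.methylation_fraction == pytest.approx(0.75)
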