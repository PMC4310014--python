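"""Energy state variables: closed-form values, algebraic identities,
monotonicity, signs and bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gendyn import (ConsistencyError, EnvironmentState, GenomeModel,
                    GendynError, Haploblock, HaplotypeDistribution,
                    IndividualGenotype, SNPSite, ValidationError,
                    allelic_potential, block_potential, derive_environment,
                    environmental_potential, fixing_potential,
                    individual_potential, nic_block, potential_difference,
                    site_potential, stability_residual)
from gendyn.simulate import SimConfig, simulate_model
from conftest import random_dirichlet_block


class TestEnvironmentalPotential:
    def test_conserved_genome_is_mu_tilde(self):
        assert environmental_potential(100, 0.0, 1.0) == 1.0

    def test_half_disordered(self):
        assert environmental_potential(100, 50.0, 1.0) == pytest.approx(2.0)

    def test_fully_disordered_rejected(self):
        with pytest.raises(GendynError):
            environmental_potential(10, 10.0)

    def test_entropy_above_count_rejected(self):
        with pytest.raises(ConsistencyError):
            environmental_potential(10, 11.0)


class TestFixingPotential:
    @pytest.mark.parametrize("te,expected", [
        (1.26, -0.26), (1.0, 0.0), (2.0, -1.0), (1.12, -0.12),
    ])
    def test_values(self, te, expected):
        assert fixing_potential(1.0, te) == pytest.approx(expected, abs=1e-12)

    def test_te_below_mu_rejected(self):
        with pytest.raises(ConsistencyError):
            fixing_potential(1.0, 0.8)


class TestAllelicPotential:
    def test_half_frequency_single_snp_is_mu_tilde(self):
        """A lone SNP at p = 1/2 sits at mu_tilde for *any* environment."""
        for te in (1.0001, 1.26, 2.0, 5.0):
            env = EnvironmentState.from_te(te)
            assert allelic_potential(0.5, 1, env) == pytest.approx(
                1.0, abs=1e-12)

    def test_fixed_allele_at_fixing_potential(self):
        env = EnvironmentState.from_te(1.26)
        assert allelic_potential(1.0, 1, env) == pytest.approx(
            -0.26, abs=1e-12)

    def test_maximally_varying_block_reaches_n_mu_tilde(self):
        env = EnvironmentState.from_te(1.25)
        assert allelic_potential((1 / 2) ** 3, 3, env) == pytest.approx(
            3.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.0001])
    def test_domain_errors(self, p):
        env = EnvironmentState.from_te(1.5)
        with pytest.raises(ValidationError):
            allelic_potential(p, 1, env)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(min_value=1.0001, max_value=10.0),
           st.integers(min_value=1, max_value=50))
    def test_strictly_decreasing_in_frequency(self, te, n):
        env = EnvironmentState.from_te(te)
        ps = np.linspace(0.01, 1.0, 25)
        pots = [allelic_potential(p, n, env) for p in ps]
        assert all(a > b for a, b in zip(pots, pots[1:]))


class TestPotentialDifference:
    def test_equal_frequencies_zero(self):
        assert potential_difference(0.3, 0.3, 1.7) == 0.0

    def test_halving_frequency_costs_te(self):
        assert potential_difference(0.5, 0.25, 1.0) == pytest.approx(1.0)

    def test_antisymmetric(self):
        assert potential_difference(0.4, 0.1, 2.0) == pytest.approx(
            -potential_difference(0.1, 0.4, 2.0), abs=1e-12)

    def test_consistent_with_allelic_potentials(self):
        rng = np.random.default_rng(5)
        env = EnvironmentState.from_te(1.8)
        for _ in range(50):
            p1, p2 = rng.uniform(0.01, 1.0, size=2)
            n = int(rng.integers(1, 20))
            direct = potential_difference(p1, p2, env.t_e)
            via = (allelic_potential(p2, n, env)
                   - allelic_potential(p1, n, env))
            assert direct == pytest.approx(via, abs=1e-9)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValidationError):
            potential_difference(0.0, 0.5, 1.0)


class TestBlockPotential:
    def test_vanishes_at_genome_nic(self, mixed_block):
        nic = nic_block(mixed_block.distribution, 2)
        env = EnvironmentState.from_nic(nic)
        assert block_potential(mixed_block, env) == pytest.approx(
            0.0, abs=1e-12)

    def test_conserved_block_against_background(self):
        dist = HaplotypeDistribution(("A" * 10,), (1.0,))
        block = Haploblock.from_distribution("B", "1", (1, 100), dist)
        env = EnvironmentState.from_nic(0.8)
        # (1 - 1/0.8) * 10 * 1 = -2.5
        assert block_potential(block, env) == pytest.approx(-2.5, abs=1e-12)

    def test_conserved_block_reaches_n_mu_fixing(self, conserved_block):
        for te in (1.26, 1.12, 2.0):
            env = EnvironmentState.from_te(te)
            n = conserved_block.effective_n()
            assert block_potential(conserved_block, env) == pytest.approx(
                n * env.mu_fixing, abs=1e-12)

    def test_dual_forms_agree_on_random_blocks(self):
        """Closed form (1 - NIC_H/NIC_G) n mu_tilde equals the independently
        recomputed frequency-weighted average of the haplotype potentials."""
        rng = np.random.default_rng(17)
        for i in range(200):
            n = int(rng.integers(1, 13))
            block = random_dirichlet_block(rng, n, block_id=f"B{i}")
            env = EnvironmentState.from_te(float(rng.uniform(1.01, 4.0)))
            nn = block.effective_n()
            weighted = sum(
                p * ((env.mu_tilde - env.t_e) * nn - env.t_e * math.log2(p))
                for p in block.distribution.freqs)
            assert block_potential(block, env) == pytest.approx(
                weighted, abs=1e-9)

    def test_monotone_decreasing_in_block_nic(self):
        from gendyn.simulate import simulate_target_nic_block
        env = EnvironmentState.from_nic(0.6)
        n = 4
        pots = []
        for target in (0.1, 0.4, 0.6, 0.8, 1.0):
            dist = simulate_target_nic_block(n, target, tol=1e-9, seed=3)
            block = Haploblock("B", "1", (1, 100), (), n, n, dist)
            pots.append(block_potential(block, env))
        assert all(a > b for a, b in zip(pots, pots[1:]))


class TestSitePotential:
    def test_matches_one_snp_block_closed_form(self):
        # NIC(S) = 0 at p = 1/2, so Eq-14 gives (1 - 0/NIC_G) * 1 * mu_tilde
        env = EnvironmentState.from_nic(0.5)
        site = SNPSite("rs", "1", 1, ("A", "G"), (0.5, 0.5))
        assert site_potential(site, env) == pytest.approx(1.0, abs=1e-12)

    def test_fixation_limit_tends_to_mu_fixing(self):
        env = EnvironmentState.from_te(1.26)
        gaps = []
        for eps in (1e-3, 1e-5, 1e-7, 1e-9):
            site = SNPSite("rs", "1", 1, ("A", "G"), (1 - eps, eps))
            gaps.append(abs(site_potential(site, env) - env.mu_fixing))
        # convergence is slow (eps*log eps) but monotone
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-7
        fixed = SNPSite("rs", "1", 1, ("A", "G"), (1.0, 0.0))
        assert site_potential(fixed, env) == pytest.approx(
            env.mu_fixing, abs=1e-12)

    def test_weighted_mean_of_allelic_potentials(self):
        rng = np.random.default_rng(23)
        env = EnvironmentState.from_te(1.7)
        for _ in range(30):
            p = float(rng.uniform(0.01, 0.99))
            site = SNPSite("rs", "1", 1, ("A", "G"), (p, 1 - p))
            expect = (p * allelic_potential(p, 1, env)
                      + (1 - p) * allelic_potential(1 - p, 1, env))
            assert site_potential(site, env) == pytest.approx(
                expect, abs=1e-12)

    def test_never_below_fixing_potential(self):
        env = EnvironmentState.from_te(2.3)
        for p in np.linspace(0.001, 0.999, 101):
            site = SNPSite("rs", "1", 1, ("A", "G"), (p, 1 - p))
            assert site_potential(site, env) >= env.mu_fixing - 1e-12


class TestStability:
    def test_self_consistent_environment_balances(self):
        for seed in (1, 7, 42):
            model = simulate_model(SimConfig(seed=seed))
            env = derive_environment(model)
            res = stability_residual(model, env)
            assert abs(res) <= 1e-6 * model.n_snps()

    def test_inflated_te_gives_negative_residual(self, toy_model):
        env0 = derive_environment(toy_model)
        env = EnvironmentState.from_te(env0.t_e * 1.5)
        assert stability_residual(toy_model, env) < 0

    def test_analytic_residual_form(self):
        """mu_Genome = mu_tilde*n - T_E*(n - s) for any environment."""
        from gendyn import genome_entropy
        model = simulate_model(SimConfig(seed=3, n_blocks=8, n_unlinked=10))
        n, s = model.n_snps(), genome_entropy(model)
        for te in (1.3, 2.0, 3.5):
            env = EnvironmentState.from_te(te)
            assert stability_residual(model, env) == pytest.approx(
                1.0 * n - te * (n - s), abs=1e-8)

    def test_sign_rule_vs_genome_nic(self):
        """Blocks more conserved than the genome have negative potential,
        more varying ones positive."""
        model = simulate_model(SimConfig(seed=9))
        env = derive_environment(model)
        for block in model.blocks:
            nic_h = nic_block(block.distribution, block.effective_n())
            mu = block_potential(block, env)
            if nic_h > env.nic_genome + 1e-12:
                assert mu < 0
            elif nic_h < env.nic_genome - 1e-12:
                assert mu > 0

    def test_block_potential_bounded_by_n_mu_tilde(self):
        model = simulate_model(SimConfig(seed=13))
        env = derive_environment(model)
        for block in model.blocks:
            assert block_potential(block, env) <= (
                block.effective_n() * env.mu_tilde + 1e-12)


class TestDeriveEnvironment:
    def test_fully_conserved_model(self):
        dist = HaplotypeDistribution(("ACGTA",), (1.0,))
        block = Haploblock.from_distribution("B", "1", (1, 100), dist)
        env = derive_environment(GenomeModel((block,), ()))
        assert env.t_e == pytest.approx(1.0, abs=1e-12)
        assert env.mu_fixing == pytest.approx(0.0, abs=1e-12)

    def test_half_nic_model(self):
        # two haplotypes differing at both sites, 50/50: s = 1, n = 2
        dist = HaplotypeDistribution(("AC", "GT"), (0.5, 0.5))
        block = Haploblock.from_distribution("B", "1", (1, 100), dist)
        env = derive_environment(GenomeModel((block,), ()))
        assert env.nic_genome == pytest.approx(0.5, abs=1e-12)
        assert env.t_e == pytest.approx(2.0, abs=1e-12)
        assert env.mu_fixing == pytest.approx(-1.0, abs=1e-12)

    def test_mu_tilde_scaling(self, toy_model):
        env1 = derive_environment(toy_model, mu_tilde=1.0)
        env2 = derive_environment(toy_model, mu_tilde=2.5)
        assert env2.t_e == pytest.approx(2.5 * env1.t_e, abs=1e-12)


class TestIndividualPotential:
    def _one_snp_model(self):
        dist = HaplotypeDistribution(("A", "G"), (0.5, 0.5))
        block = Haploblock.from_distribution("B1", "1", (10, 10), dist)
        return GenomeModel((block,), ())

    def test_half_frequency_strands(self):
        model = self._one_snp_model()
        env = EnvironmentState.from_te(2.0)
        geno = IndividualGenotype("ind1", {"B1": ("A", "A")}, {})
        pot = individual_potential(geno, model, env)
        assert pot.strand_GEU[0] == pytest.approx(1.0, abs=1e-12)
        assert pot.diploid_GEU == pytest.approx(2.0, abs=1e-12)

    def test_all_fixed_alleles_give_n_mu_fixing(self):
        dist = HaplotypeDistribution(("ACG",), (1.0,))
        block = Haploblock.from_distribution("B1", "1", (1, 30), dist)
        model = GenomeModel((block,), ())
        env = EnvironmentState.from_te(1.26)
        geno = IndividualGenotype("ind1", {"B1": ("ACG", "ACG")}, {})
        pot = individual_potential(geno, model, env)
        assert pot.strand_GEU[0] == pytest.approx(3 * env.mu_fixing,
                                                  abs=1e-12)

    def test_unobserved_haplotype_rejected(self):
        model = self._one_snp_model()
        env = EnvironmentState.from_te(2.0)
        geno = IndividualGenotype("ind1", {"B1": ("T", "A")}, {})
        with pytest.raises(GendynError):
            individual_potential(geno, model, env)

    def test_population_mean_equals_potential_sum(self, mixed_block,
                                                  half_snp):
        """Enumerating every (haplotype, allele) strand with its probability,
        the weighted mean strand potential equals the block+site potential
        sum of the stability condition."""
        model = GenomeModel((mixed_block,), (half_snp,))
        env = derive_environment(model)
        mean = 0.0
        for hap, ph in mixed_block.distribution.items():
            for allele, pa in zip(half_snp.alleles, half_snp.freqs):
                geno = IndividualGenotype(
                    "x", {"B1": (hap, hap)}, {"rs1": (allele, allele)})
                pot = individual_potential(geno, model, env)
                mean += ph * pa * pot.strand_GEU[0]
        expect = (block_potential(mixed_block, env)
                  + site_potential(half_snp, env))
        assert mean == pytest.approx(expect, abs=1e-9)
        # and for the self-consistent environment that sum is zero
        assert mean == pytest.approx(0.0, abs=1e-9)
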