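"""The synthetic admixed-cohort generator."""

import numpy as np
import pytest

from laspa import (
    CausalRegion,
    SimulationConfig,
    ValidationError,
    adjust_phenotype,
    compute_global_pcs,
    impute_missing,
    simulate_ancestral_freqs,
    simulate_cohort,
    simulate_genotypes,
)


class TestAncestralFreqs:
    def test_balding_nichols_fst_recovered(self):
        """Weir–Cockerham-style estimate over SNVs ≈ the configured F."""
        cfg = SimulationConfig(n_subjects=10, n_chromosomes=1, snvs_per_chromosome=10_000,
                               n_ancestries=2, fst=0.2, target_rare_fraction=0.3, seed=1)
        rng = np.random.default_rng(1)
        freqs = simulate_ancestral_freqs(cfg, rng)
        # moment estimator: E[s²] = F p(1-p) and E[p̄(1-p̄)] = p(1-p)(1-F/2)
        # for 2 populations, so F̂ = Σs² / Σ(p̄(1-p̄) + s²/2)
        pbar = freqs.mean(axis=0)
        ok = (pbar > 0.05) & (pbar < 0.95)
        s2 = freqs.var(axis=0, ddof=1)[ok]
        den = (pbar * (1 - pbar))[ok] + s2 / 2
        assert s2.sum() / den.sum() == pytest.approx(0.2, abs=0.02)

    def test_tiny_fst_collapses_to_ancestral(self):
        cfg = SimulationConfig(n_subjects=10, n_chromosomes=1, snvs_per_chromosome=2_000,
                               n_ancestries=3, fst=1e-4, seed=2)
        rng = np.random.default_rng(2)
        freqs = simulate_ancestral_freqs(cfg, rng)
        assert freqs.std(axis=0).max() < 0.02

    def test_frequencies_in_unit_interval(self):
        cfg = SimulationConfig(n_subjects=10, n_chromosomes=1, snvs_per_chromosome=5_000, seed=3)
        freqs = simulate_ancestral_freqs(cfg, np.random.default_rng(3))
        assert freqs.min() >= 0.0 and freqs.max() <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError, match="fst"):
            SimulationConfig(fst=1.5)
        with pytest.raises(ValidationError, match="rare_fraction"):
            SimulationConfig(target_rare_fraction=1.0)
        with pytest.raises(ValidationError, match="alpha"):
            SimulationConfig(n_ancestries=3, admixture_alpha=(1.0, 1.0))


class TestGenotypes:
    def test_degenerate_proportions_match_single_ancestry_freqs(self):
        cfg = SimulationConfig(n_subjects=400, n_chromosomes=1, snvs_per_chromosome=300,
                               admixture_alpha=(1e-6, 1e-6, 1.0), missing_rate=0.0, seed=4)
        rng = np.random.default_rng(4)
        freqs = simulate_ancestral_freqs(cfg, rng)
        g, truth = simulate_genotypes(cfg, freqs, rng)
        assert (truth.local_ancestry == 2).all()
        sample_f = g.dosages.mean(axis=0) / 2
        common = freqs[2] > 0.1
        assert np.corrcoef(sample_f[common], freqs[2][common])[0, 1] > 0.98

    def test_no_missing_when_rate_zero(self):
        cfg = SimulationConfig(n_subjects=50, n_chromosomes=1, snvs_per_chromosome=200,
                               missing_rate=0.0, seed=5)
        g, _, _ = simulate_cohort(cfg)
        assert not g.has_missing

    def test_missing_rate_realized(self, fixture_cohort):
        g, _, _ = fixture_cohort
        rate = (g.dosages == -1).mean()
        assert rate == pytest.approx(0.01, abs=0.003)

    def test_seeded_determinism(self):
        cfg = SimulationConfig(n_subjects=30, n_chromosomes=1, snvs_per_chromosome=100, seed=6)
        g1, p1, t1 = simulate_cohort(cfg)
        g2, p2, t2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        np.testing.assert_allclose(p1.table["trait"], p2.table["trait"])
        np.testing.assert_array_equal(t1.local_ancestry, t2.local_ancestry)

    def test_truth_dimensions(self, fixture_cohort, fixture_config):
        g, pheno, truth = fixture_cohort
        assert truth.local_ancestry.shape == (g.n_subjects, len(fixture_config.region_blocks()))
        assert truth.global_proportions.shape == (g.n_subjects, 3)
        np.testing.assert_allclose(truth.global_proportions.sum(axis=1), 1.0)


class TestPhenotype:
    def test_null_effects_give_pure_noise(self):
        cfg = SimulationConfig(n_subjects=2000, n_chromosomes=1, snvs_per_chromosome=200,
                               beta_age=0.0, beta_sex=0.0, beta_medication=(0.0, 0.0, 0.0),
                               global_ancestry_effect=0.0, noise_sd=1.0,
                               missing_rate=0.0, seed=7)
        g, pheno, _ = simulate_cohort(cfg)
        pcs = compute_global_pcs(g, 1)
        adj = adjust_phenotype(pheno, pcs.scores[:, 0])
        assert adj.r_squared < 0.01

    def test_default_effects_explain_about_a_quarter(self):
        """Default covariate/ancestry effect sizes target R² ≈ 0.25 at large n."""
        cfg = SimulationConfig(n_subjects=3000, n_chromosomes=1, snvs_per_chromosome=1500,
                               n_ancestries=2, fst=0.2, admixture_alpha=(5.0, 5.0),
                               missing_rate=0.0, seed=8)
        g, pheno, truth = simulate_cohort(cfg)
        pcs = compute_global_pcs(g, 1)
        # PC1 tracks the admixture proportion
        assert abs(np.corrcoef(pcs.scores[:, 0], truth.global_proportions[:, 0])[0, 1]) > 0.5
        # analytic: age 48 + sex 2.25 + med 3.96 + γ² Var(prop1) vs noise 196
        v = 48 + 2.25 + 3.96 + 20.0**2 * truth.global_proportions[:, 0].var()
        expected = v / (v + 14.0**2)
        adj = adjust_phenotype(pheno, pcs.scores[:, 0])
        assert adj.r_squared == pytest.approx(expected, abs=0.035)
        assert 0.19 < adj.r_squared < 0.31

    def test_causal_region_effects_recorded(self):
        cfg = SimulationConfig(n_subjects=300, n_chromosomes=1, snvs_per_chromosome=1000,
                               missing_rate=0.0, seed=9,
                               causal_region=CausalRegion(1, (5.0, -5.0, 0.0), 10))
        g, pheno, truth = simulate_cohort(cfg)
        assert truth.causal_variant_indices is not None
        assert (truth.causal_variant_indices >= 500).all()
        assert (truth.causal_variant_indices < 1000).all()
        assert truth.genetic_effects.shape == (300,)
        assert truth.genetic_effects.any()

    def test_causal_region_out_of_range(self):
        cfg = SimulationConfig(n_subjects=50, n_chromosomes=1, snvs_per_chromosome=600,
                               missing_rate=0.0, seed=10,
                               causal_region=CausalRegion(7, (1.0, 1.0, 1.0)))
        with pytest.raises(ValidationError, match="out of range"):
            simulate_cohort(cfg)
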