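"""Synthetic cohort generator: LD structure, MAF control, planted-effect
recovery, conditional independence of mediated chains, null calibration."""

import numpy as np
import pytest
from scipy import stats

from trimetaqtl.assoc import fit_ols, genomic_lambda, scan_ols
from trimetaqtl.simulate import (
    PlantedEffect,
    SimConfig,
    TruthTable,
    default_effects,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_metabolites,
    simulate_study,
)


def pairwise_r2(doses):
    r = np.corrcoef(doses, rowvar=False)
    return r**2


class TestGenotypes:
    def test_unit_blocks_are_independent(self):
        cfg = SimConfig(n_snps=60, ld_block_size=1, seed=5)
        G = simulate_genotypes(2000, cfg)
        r2 = pairwise_r2(G.doses)
        np.fill_diagonal(r2, 0.0)
        assert np.nanmax(r2) < 0.05

    def test_within_block_ld_exceeds_between(self):
        cfg = SimConfig(n_snps=50, ld_block_size=5, seed=6)
        G = simulate_genotypes(2000, cfg)
        r2 = pairwise_r2(G.doses)
        within, between = [], []
        for i in range(50):
            for j in range(i + 1, 50):
                (within if i // 5 == j // 5 else between).append(r2[i, j])
        assert np.mean(within) > 10 * np.mean(between)
        assert max(between) < 0.05

    def test_maf_matches_target(self):
        cfg = SimConfig(n_snps=40, ld_block_size=1, maf_range=(0.3, 0.3), seed=7)
        n = 2000
        G = simulate_genotypes(n, cfg)
        bound = 3 * np.sqrt(0.3 * 0.7 / (2 * n))
        for j, snp in enumerate(G.snps):
            af = G.doses[:, j].mean() / 2
            emp_maf = min(af, 1 - af)
            # founder-pool rounding quantizes frequency to 1/pool steps
            assert abs(emp_maf - snp.maf) < bound + 0.02
            assert abs(emp_maf - 0.3) < bound + 1 / cfg.haplotype_pool

    def test_doses_in_range_and_info_populated(self):
        G = simulate_genotypes(200, SimConfig(n_snps=30, seed=8))
        assert G.doses.min() >= 0 and G.doses.max() <= 2
        assert all(0.9 <= s.info <= 1.0 for s in G.snps)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            simulate_genotypes(1, SimConfig(n_snps=10, seed=0))


class TestExpression:
    def _setup(self, beta, n=2000, batch_sd=0.0, seed=11):
        cfg = SimConfig(n_snps=20, n_probes=10, batch_shift_sd=batch_sd, seed=seed)
        G = simulate_genotypes(n, cfg)
        effects = [PlantedEffect("snp_probe_cis", snp_id="snp0001",
                                 probe_id="probe001", beta=beta)] if beta else []
        truth = TruthTable(effects)
        E, batch = simulate_expression(G, truth, cfg)
        return G, E, batch

    def test_null_expression_uncorrelated_with_doses(self):
        G, E, _ = self._setup(beta=0.0, n=1000)
        r = np.corrcoef(np.column_stack([G.doses[:, :5], E.values[:, :5]]),
                        rowvar=False)[:5, 5:]
        assert np.max(np.abs(r)) < 3 / np.sqrt(1000) * 1.8

    def test_planted_cis_effect_recovered(self):
        G, E, _ = self._setup(beta=0.5)
        fit = fit_ols(E.expression("probe001"), G.dose("snp0001"))
        assert abs(fit.beta - 0.5) < 3 * fit.se

    def test_zero_batch_sd_no_batch_separation(self):
        G, E, batch = self._setup(beta=0.0, n=1000, batch_sd=0.0)
        a, b = E.values[batch == 0], E.values[batch == 1]
        diff = a.mean(axis=0) - b.mean(axis=0)
        se = np.sqrt(a.var(axis=0) / len(a) + b.var(axis=0) / len(b))
        assert np.all(np.abs(diff) < 3.5 * se)

    def test_cis_probe_within_window(self):
        cfg = SimConfig(n_snps=20, n_probes=5, seed=3)
        G = simulate_genotypes(500, cfg)
        truth = TruthTable([PlantedEffect("snp_probe_cis", snp_id="snp0001",
                                          probe_id="probe001", beta=0.4)])
        E, _ = simulate_expression(G, truth, cfg)
        snp = G.snp("snp0001")
        probe = E.probe("probe001")
        assert probe.chrom == snp.chrom
        assert abs(snp.pos - probe.center) <= 1_000_000


class TestMetabolites:
    def test_mediated_chain_conditional_independence(self):
        """Pure mediation: SNP and metabolite are conditionally independent
        given the transcript."""

        n = 2000
        cfg = SimConfig(n_snps=20, n_probes=5, n_metabolites=6, seed=21,
                        batch_shift_sd=0.0)
        G = simulate_genotypes(n, cfg)
        truth = TruthTable([
            PlantedEffect("snp_probe_cis", snp_id="snp0001", probe_id="probe001", beta=0.7),
            PlantedEffect("probe_metab", probe_id="probe001", metabolite="M01", beta=0.5),
        ])
        E, _ = simulate_expression(G, truth, cfg)
        C = simulate_covariates(n, np.random.default_rng(1))
        panel = simulate_metabolites(G, E, C, truth, cfg)
        y = np.log(panel.column("M01"))  # latent scale
        g, e = G.dose("snp0001"), E.expression("probe001")
        marginal = fit_ols(y, g)
        assert marginal.p < 1e-10  # the chain induces a marginal association
        partial = fit_ols(y, g, e[:, None])
        assert abs(partial.t) < 3.0  # vanishes given expression

    def test_null_scan_uniform_pvalues(self):
        n = 400
        cfg = SimConfig(n_snps=500, ld_block_size=1, n_probes=2,
                        n_metabolites=4, seed=22, batch_shift_sd=0.0)
        G = simulate_genotypes(n, cfg)
        truth = TruthTable([])
        E, _ = simulate_expression(G, truth, cfg)
        C = simulate_covariates(n, np.random.default_rng(2))
        panel = simulate_metabolites(G, E, C, truth, cfg)
        y = np.log(panel.values)
        p = scan_ols(y, G.doses, C)["p"].ravel()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_lod_fraction(self):
        cfg = SimConfig(n_snps=10, n_probes=2, n_metabolites=4, n_high_lod=1,
                        high_lod_quantile=0.3, seed=23)
        G = simulate_genotypes(1000, cfg)
        truth = TruthTable([])
        E, _ = simulate_expression(G, truth, cfg)
        C = simulate_covariates(1000, np.random.default_rng(3))
        panel = simulate_metabolites(G, E, C, truth, cfg)
        frac = panel.below_lod[:, -1].mean()
        assert abs(frac - 0.30) < 0.03


class TestStudy:
    def test_seed_determinism(self):
        cfg = SimConfig(n_discovery=100, n_replication=50, n_snps=30,
                        n_probes=12, n_metabolites=12, seed=9)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        assert np.array_equal(a.discovery.genotypes.doses, b.discovery.genotypes.doses)
        assert np.array_equal(a.discovery.metabolites.values,
                              b.discovery.metabolites.values)
        assert np.array_equal(a.replication.expression.values,
                              b.replication.expression.values)
        c = simulate_study(SimConfig(**{**cfg.__dict__, "seed": 10}))
        assert not np.array_equal(a.discovery.genotypes.doses,
                                  c.discovery.genotypes.doses)

    def test_replication_recovers_planted_effect(self, small_study):
        rep = small_study.replication
        y = np.log(rep.metabolites.column("M01"))
        # the planted SNP may have been dropped from the replication panel;
        # its block mates (r^2 ~ 1) carry the same signal
        present = set(rep.genotypes.snp_ids)
        snp = next(s for s in ("snp0001", "snp0002", "snp0003", "snp0004", "snp0005")
                   if s in present)
        fit = fit_ols(y, rep.genotypes.dose(snp))
        assert abs(fit.beta - 0.6) < 4 * fit.se

    def test_replication_drops_snps(self, small_study):
        n_disc = len(small_study.discovery.genotypes.snps)
        n_rep = len(small_study.replication.genotypes.snps)
        assert n_rep == n_disc - round(0.10 * n_disc)

    def test_null_scan_lambda_bounded(self):
        n = 800
        cfg = SimConfig(n_snps=500, ld_block_size=5, n_probes=2,
                        n_metabolites=4, seed=31, batch_shift_sd=0.0)
        G = simulate_genotypes(n, cfg)
        truth = TruthTable([])
        E, _ = simulate_expression(G, truth, cfg)
        C = simulate_covariates(n, np.random.default_rng(4))
        panel = simulate_metabolites(G, E, C, truth, cfg)
        p = scan_ols(np.log(panel.values), G.doses, C)["p"].ravel()
        assert 0.9 <= genomic_lambda(p) <= 1.1

    def test_variance_explained_consistency(self):
        """beta^2 Var(dose) / Var(metabolite latent) matches the regression
        R^2 within 20% relative error."""

        n = 2000
        cfg = SimConfig(n_snps=10, n_probes=2, n_metabolites=2, seed=32,
                        batch_shift_sd=0.0)
        G = simulate_genotypes(n, cfg)
        truth = TruthTable([PlantedEffect("snp_metab_direct", snp_id="snp0001",
                                          metabolite="M01", beta=0.6)])
        E, _ = simulate_expression(G, truth, cfg)
        C = simulate_covariates(n, np.random.default_rng(5))
        panel = simulate_metabolites(G, E, C, truth, cfg)
        y = np.log(panel.column("M01"))
        g = G.dose("snp0001")
        expected = 0.6**2 * g.var() / y.var()
        fit = fit_ols(y, g)
        assert abs(fit.explained_var - expected) / expected < 0.2

    def test_default_design_has_twenty_effects(self):
        cfg = SimConfig()
        effects = default_effects(cfg)
        substantive = [e for e in effects if e.kind != "snp_probe_metab_mediated"]
        assert len(substantive) == 20
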