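"""mQTL scan, LD pruning (with a brute-force oracle), locus assignment,
proxy search and direction-consistent replication."""

import numpy as np
import pandas as pd
import pytest

from trimetaqtl.datatypes import GenotypeMatrix, SnpRecord
from trimetaqtl.metabolites import prepare_panel
from trimetaqtl.mqtl import (
    assign_loci,
    find_proxies,
    ld_r2,
    prune_lead_snps,
    replicate,
    run_mqtl_scan,
)

from conftest import make_panel


def make_genotypes(doses, positions=None, chrom=None, info=None):
    doses = np.asarray(doses, dtype=float)
    n, m = doses.shape
    positions = positions or [1 + j * 10_000 for j in range(m)]
    chrom = chrom or ["1"] * m
    info = info or [1.0] * m
    snps = [SnpRecord(f"rs{j}", chrom[j], positions[j], maf=0.3, info=info[j])
            for j in range(m)]
    return GenotypeMatrix([f"S{i:05d}" for i in range(n)], snps, doses)


class TestLdR2:
    def test_self_is_one(self, rng):
        G = make_genotypes(rng.binomial(2, 0.3, (200, 2)).astype(float))
        assert ld_r2(G, "rs0", "rs0") == pytest.approx(1.0)

    def test_independent_snps_low(self, rng):
        G = make_genotypes(rng.binomial(2, 0.3, (2000, 2)).astype(float))
        assert ld_r2(G, "rs0", "rs1") < 0.01

    def test_noisy_duplicate_high(self, rng):
        a = rng.binomial(2, 0.3, 2000).astype(float)
        b = np.clip(a + rng.normal(0, 0.05, 2000), 0, 2)
        G = make_genotypes(np.column_stack([a, b]))
        assert ld_r2(G, "rs0", "rs1") > 0.98

    def test_monomorphic_raises(self, rng):
        G = make_genotypes(np.column_stack(
            [np.ones(50), rng.binomial(2, 0.3, 50).astype(float)]))
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(G, "rs0", "rs1")


def greedy_prune_oracle(snp_order, r2):
    """Independent brute-force implementation of the greedy rule."""

    retained = []
    for s in snp_order:
        if all(r2[s, r] < 0.3 for r in retained):
            retained.append(s)
    return retained


class TestPrune:
    def _top(self, snp_ids, pvals):
        return pd.DataFrame(
            {"x_id": snp_ids, "y_id": "M1", "layer": "mqtl", "beta": 0.1,
             "se": 0.01, "t": 10.0, "p": pvals, "q": np.nan, "n": 100,
             "df": 95, "explained_var": 0.1}
        )

    def test_single_snp_retained(self, rng):
        G = make_genotypes(rng.binomial(2, 0.3, (100, 1)).astype(float))
        leads = prune_lead_snps(self._top(["rs0"], [1e-9]), G)
        assert leads.snp_ids == ["rs0"]

    def test_perfect_ld_keeps_smaller_p(self, rng):
        a = rng.binomial(2, 0.3, 500).astype(float)
        G = make_genotypes(np.column_stack([a, a]))
        leads = prune_lead_snps(self._top(["rs0", "rs1"], [1e-8, 1e-9]), G)
        assert leads.snp_ids == ["rs1"]

    def test_matches_brute_force_oracle(self, rng):
        """5-SNP constructed LD structure: greedy result equals enumeration."""

        n = 1000
        base1 = rng.binomial(2, 0.3, n).astype(float)
        base2 = rng.binomial(2, 0.4, n).astype(float)
        doses = np.column_stack([
            base1,
            np.clip(base1 + rng.normal(0, 0.1, n), 0, 2),   # ~r2=0.95 with 0
            base2,
            np.clip(base2 + rng.normal(0, 0.3, n), 0, 2),   # moderate LD with 2
            rng.binomial(2, 0.25, n).astype(float),          # independent
        ])
        G = make_genotypes(doses)
        pvals = [1e-10, 1e-12, 1e-9, 1e-13, 1e-8]
        leads = prune_lead_snps(self._top([f"rs{j}" for j in range(5)], pvals), G)
        r2 = np.corrcoef(doses, rowvar=False) ** 2
        order = np.argsort(pvals)
        expected = [f"rs{j}" for j in greedy_prune_oracle(order, r2)]
        assert sorted(leads.snp_ids) == sorted(expected)
        # invariant: pruned set has max pairwise r2 < 0.3
        for i, a in enumerate(leads.snp_ids):
            for b in leads.snp_ids[i + 1:]:
                assert ld_r2(G, a, b) < 0.3
        # every discarded SNP is tagged by a retained SNP of <= p
        pmap = dict(zip([f"rs{j}" for j in range(5)], pvals))
        for s in set(G.snp_ids) - set(leads.snp_ids):
            assert any(
                ld_r2(G, s, r) >= 0.3 and pmap[r] <= pmap[s] for r in leads.snp_ids
            )


class TestAssignLoci:
    def _leads(self, rng, positions, chroms):
        m = len(positions)
        G = make_genotypes(rng.binomial(2, 0.3, (100, m)).astype(float),
                           positions=positions, chrom=chroms)
        top = pd.DataFrame(
            {"x_id": [f"rs{j}" for j in range(m)], "y_id": "M1", "layer": "mqtl",
             "beta": 0.1, "se": 0.01, "t": 10.0, "p": [1e-9] * m, "q": np.nan,
             "n": 100, "df": 95, "explained_var": 0.1}
        )
        return prune_lead_snps(top, G, r2_max=1.1)  # keep all

    def test_nearby_leads_merge(self, rng):
        leads = assign_loci(self._leads(rng, [1_000_000, 1_500_000], ["1", "1"]))
        assert leads.leads["locus_id"].nunique() == 1

    def test_different_chromosomes_split(self, rng):
        leads = assign_loci(self._leads(rng, [1_000_000, 1_000_000], ["1", "2"]))
        assert leads.leads["locus_id"].nunique() == 2

    def test_single_linkage_chain(self, rng):
        positions = [1_000_000, 1_900_000, 2_800_000]  # A-B 0.9Mb, B-C 0.9Mb
        leads = assign_loci(self._leads(rng, positions, ["1"] * 3))
        assert leads.leads["locus_id"].nunique() == 1


class TestProxies:
    def test_lead_is_its_own_proxy(self, rng):
        doses = rng.binomial(2, 0.3, (500, 2)).astype(float)
        G = make_genotypes(doses)
        proxies = find_proxies(["rs0"], G, G)
        row = proxies.iloc[0]
        assert row.proxy_snp_id == "rs0" and row.r2 == pytest.approx(1.0)

    def test_outside_window_rejected(self, rng):
        a = rng.binomial(2, 0.3, 500).astype(float)
        doses = np.column_stack([a, np.clip(a + rng.normal(0, 0.05, 500), 0, 2)])
        G_disc = make_genotypes(doses, positions=[100_000, 160_000])  # 60 kb apart
        G_rep = G_disc.subset_snps(["rs1"])
        assert find_proxies(["rs0"], G_disc, G_rep).empty

    def test_weak_ld_rejected(self, rng):
        a = rng.binomial(2, 0.3, 2000).astype(float)
        b = np.clip(0.7 * a + rng.normal(0, 0.7, 2000), 0, 2)  # r2 ~ 0.5
        G_disc = make_genotypes(np.column_stack([a, b]), positions=[100_000, 110_000])
        assert ld_r2(G_disc, "rs0", "rs1") < 0.8
        G_rep = G_disc.subset_snps(["rs1"])
        assert find_proxies(["rs0"], G_disc, G_rep).empty

    def test_low_info_rejected(self, rng):
        a = rng.binomial(2, 0.3, 500).astype(float)
        doses = np.column_stack([a, a])
        G_disc = make_genotypes(doses, positions=[100_000, 110_000])
        G_rep = make_genotypes(doses, positions=[100_000, 110_000],
                               info=[1.0, 0.2]).subset_snps(["rs1"])
        assert find_proxies(["rs0"], G_disc, G_rep).empty


class TestReplicate:
    def _pair_frame(self, snp, metab, beta):
        return pd.DataFrame(
            {"x_id": [snp], "y_id": [metab], "layer": "mqtl", "beta": [beta],
             "se": 0.02, "t": beta / 0.02, "p": 1e-9, "q": np.nan, "n": 500,
             "df": 495, "explained_var": 0.05}
        )

    def test_planted_effect_replicates(self, small_study):
        disc, rep = small_study.discovery, small_study.replication
        panel = prepare_panel(rep.metabolites, [])
        proxies = find_proxies(["snp0001"], disc.genotypes, rep.genotypes)
        assert not proxies.empty
        out = replicate(self._pair_frame("snp0001", "M01", 0.6), proxies,
                        disc.genotypes, rep.genotypes, panel,
                        rep.covariates.select(["age", "sex"]),
                        n_perm=100, seed=1)
        assert bool(out.iloc[0].direction_consistent)
        assert bool(out.iloc[0].replicated)

    def test_discovery_only_artifact_null_in_replication(self, small_study):
        disc, rep = small_study.discovery, small_study.replication
        panel = prepare_panel(rep.metabolites, [])
        # M05 has no planted effect: a spurious discovery pair should not
        # show a real replication effect
        lead = "snp0006"
        proxies = find_proxies([lead], disc.genotypes, rep.genotypes)
        out = replicate(self._pair_frame(lead, "M05", 0.4), proxies,
                        disc.genotypes, rep.genotypes, panel,
                        rep.covariates.select(["age", "sex"]),
                        n_perm=50, seed=2)
        row = out.iloc[0]
        assert abs(row.beta_rep) < 3 * row.se_rep
        assert not row.replicated

    def test_negative_orientation_corrected(self, rng):
        """A proxy anticorrelated with the lead flips the sign of the
        replication beta; orientation restores direction consistency."""

        n = 1500
        lead = rng.binomial(2, 0.4, n).astype(float)
        proxy = 2.0 - lead  # r = -1
        G_disc = make_genotypes(np.column_stack([lead, proxy]),
                                positions=[100_000, 105_000])
        rng2 = np.random.default_rng(9)
        lead_rep = rng2.binomial(2, 0.4, n).astype(float)
        proxy_rep = 2.0 - lead_rep
        G_rep = make_genotypes(np.column_stack([lead_rep, proxy_rep]),
                               positions=[100_000, 105_000]).subset_snps(["rs1"])
        y = 0.5 * lead_rep + rng2.normal(0, 1, n)
        panel = make_panel(np.exp(y), names=["M1"])
        panel = panel.replace(stage="transformed")
        panel = panel.replace(values=np.log(panel.values), stage="masked")
        proxies = find_proxies(["rs0"], G_disc, G_rep)
        out = replicate(self._pair_frame("rs0", "M1", 0.5), proxies,
                        G_disc, G_rep, panel, None, n_perm=50, seed=3)
        row = out.iloc[0]
        assert row.orientation == -1.0
        assert row.beta_rep < 0  # raw sign flipped by the proxy coding
        assert bool(row.direction_consistent)


def test_scan_top_list_and_row_order_invariance(small_study):
    disc = small_study.discovery
    panel = prepare_panel(disc.metabolites, [])
    C = disc.covariates
    full, top = run_mqtl_scan(disc.genotypes, panel, C)
    planted = set(zip(top["x_id"], top["y_id"]))
    assert ("snp0001", "M01") in planted
    # permuting the sample order leaves every p identical
    perm = np.random.default_rng(0).permutation(len(disc.genotypes.sample_ids))
    ids = [disc.genotypes.sample_ids[i] for i in perm]
    full2, _ = run_mqtl_scan(
        disc.genotypes.subset_samples(ids), panel.subset_samples(ids),
        C.subset_samples(ids),
    )
    merged = full.merge(full2, on=["x_id", "y_id"], suffixes=("_a", "_b"))
    assert np.allclose(merged["p_a"], merged["p_b"], atol=1e-10, equal_nan=True)
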