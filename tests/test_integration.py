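"""cis/trans classification, eQTL and expression–metabolite scans, triangle
construction, the permutation/Poisson null and network assembly."""

import numpy as np
import pandas as pd
import pytest

from trimetaqtl.datatypes import (
    AssociationRecord,
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    ProbeRecord,
    SnpRecord,
    TriangleRecord,
    ValidationError,
)
from trimetaqtl.integration import (
    build_network,
    build_triangles,
    classify_cis_trans,
    discovery_triangle_analysis,
    poisson_tail_p,
    run_eqtl_scan,
    run_expr_metab_scan,
    triangle_permutation_null,
)
from trimetaqtl.metabolites import prepare_panel
from trimetaqtl.simulate import (
    PlantedEffect,
    SimConfig,
    TruthTable,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_metabolites,
    simulate_study,
)

from conftest import make_panel


class TestCisTrans:
    SNP = SnpRecord("rs1", "1", 5_000_000)

    def probe_at(self, center, chrom="1"):
        return ProbeRecord("p1", "G1", chrom, int(center) - 500, int(center) + 500)

    def test_exactly_one_mb_is_cis(self):
        assert classify_cis_trans(self.SNP, self.probe_at(6_000_000)) == "cis"

    def test_one_bp_past_window_is_trans(self):
        assert classify_cis_trans(self.SNP, self.probe_at(6_000_001)) == "trans"

    def test_other_chromosome_is_trans(self):
        assert classify_cis_trans(self.SNP, self.probe_at(5_000_000, "2")) == "trans"

    def test_missing_coordinates_raise(self):
        with pytest.raises(ValueError):
            classify_cis_trans(SnpRecord("rs1", "NA", 5), self.probe_at(10))


class TestEqtlScan:
    def test_planted_effect_detected_with_expected_r2(self):
        """A planted cis effect sized for ~13% explained variance is found
        with partial R^2 in [0.10, 0.16] at n = 2000."""

        n = 2000
        cfg = SimConfig(n_snps=20, n_probes=30, seed=41, batch_shift_sd=0.0)
        G = simulate_genotypes(n, cfg)
        truth = TruthTable([PlantedEffect("snp_probe_cis", snp_id="snp0001",
                                          probe_id="probe001", beta=0.6)])
        E, _ = simulate_expression(G, truth, cfg)
        res = run_eqtl_scan(["snp0001", "snp0006"], G, E)
        hit = res[(res.x_id == "snp0001") & (res.y_id == "probe001")].iloc[0]
        assert bool(hit.significant)
        assert hit.layer == "eqtl_cis"
        assert 0.10 <= hit.explained_var <= 0.16

    def test_explained_var_definition(self, rng):
        n = 300
        cfg = SimConfig(n_snps=10, n_probes=8, seed=42)
        G = simulate_genotypes(n, cfg)
        E, _ = simulate_expression(G, TruthTable([]), cfg)
        res = run_eqtl_scan(["snp0001"], G, E)
        ev = res["t"] ** 2 / (res["t"] ** 2 + res["df"])
        assert np.allclose(res["explained_var"], ev, atol=1e-12)

    def test_null_grid_calibrated(self):
        n = 400
        cfg = SimConfig(n_snps=250, ld_block_size=1, n_probes=100, seed=43,
                        batch_shift_sd=0.0)
        G = simulate_genotypes(n, cfg)
        E, _ = simulate_expression(G, TruthTable([]), cfg)
        snps = [s.snp_id for s in G.snps[:50]]
        res = run_eqtl_scan(snps, G, E)
        m = len(res)
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / m) + 0.005
        # BH at 5% on a pure-null grid rejects (almost) nothing
        assert res["significant"].sum() <= 2


class TestExprMetabScan:
    def test_planted_link_significant_and_grid_respected(self, rng):
        n = 1500
        expr = rng.normal(0, 1, (n, 3))
        latent = 0.3 * expr[:, 0]
        vals = np.column_stack([
            np.exp(latent + rng.normal(0, 1, n)),
            np.exp(rng.normal(0, 1, n)),
        ])
        panel = prepare_panel(make_panel(vals, names=["M1", "M2"]), [])
        probes = [ProbeRecord(f"p{j}", f"G{j}", "1", 1, 100) for j in range(3)]
        E = ExpressionMatrix([f"S{i}" for i in range(n)], probes, expr)
        res = run_expr_metab_scan(["p0", "p1"], E, panel, None)
        hit = res[(res.x_id == "p0") & (res.y_id == "M1")].iloc[0]
        assert bool(hit.significant) and hit.q <= 0.05
        null_rows = res[(res.x_id == "p1")]
        assert (np.abs(null_rows["beta"]) < 3 * null_rows["se"]).all()
        # restricting the grid changes the BH threshold context
        res_pairs = run_expr_metab_scan(["p0", "p1"], E, panel, None,
                                        pairs=[("p0", "M1")])
        assert len(res_pairs) == 1

    def test_empty_probe_list(self, rng):
        panel = prepare_panel(make_panel(np.exp(rng.normal(0, 1, (20, 2)))), [])
        E = ExpressionMatrix(
            [f"S{i:04d}" for i in range(20)],
            [ProbeRecord("p0", "G0", "1", 1, 10)], rng.normal(0, 1, (20, 1)),
        )
        assert run_expr_metab_scan([], E, panel, None).empty


def _assoc_row(x, y, layer, p=1e-9):
    return {"x_id": x, "y_id": y, "layer": layer, "beta": 0.5, "se": 0.05,
            "t": 10.0, "p": p, "q": 0.001, "n": 100, "df": 95,
            "explained_var": 0.1, "significant": True}


class TestBuildTriangles:
    def test_single_closure(self):
        mq = pd.DataFrame([_assoc_row("rs1", "M1", "mqtl")])
        eq = pd.DataFrame([_assoc_row("rs1", "p1", "eqtl_cis")])
        em = pd.DataFrame([_assoc_row("p1", "M1", "expr_metab")])
        tri = build_triangles(mq, eq, em)
        assert len(tri) == 1
        assert (tri[0].snp_id, tri[0].probe_id, tri[0].metabolite) == ("rs1", "p1", "M1")

    def test_missing_edge_no_triangle(self):
        mq = pd.DataFrame([_assoc_row("rs1", "M1", "mqtl")])
        eq = pd.DataFrame([_assoc_row("rs1", "p1", "eqtl_cis")])
        em = pd.DataFrame([_assoc_row("p2", "M1", "expr_metab")])
        assert build_triangles(mq, eq, em) == []

    def test_exhaustive_two_by_two_gives_four(self):
        mq = pd.DataFrame([_assoc_row("rs1", m, "mqtl") for m in ("M1", "M2")])
        eq = pd.DataFrame([_assoc_row("rs1", p, "eqtl_cis") for p in ("p1", "p2")])
        em = pd.DataFrame([_assoc_row(p, m, "expr_metab")
                           for p in ("p1", "p2") for m in ("M1", "M2")])
        tri = build_triangles(mq, eq, em, mode="exhaustive")
        assert len(tri) == 4

    def test_triangle_edges_validate_ids(self):
        good = AssociationRecord("rs1", "M1", "mqtl", 0.5, 0.05, 10.0, 1e-9, 100, 0.1)
        eq = AssociationRecord("rs1", "p1", "eqtl_cis", 0.5, 0.05, 10.0, 1e-9, 100, 0.1)
        em = AssociationRecord("p1", "M2", "expr_metab", 0.5, 0.05, 10.0, 1e-9, 100, 0.1)
        with pytest.raises(ValidationError):
            TriangleRecord("rs1", "p1", "M1", good, eq, em, "cis")


class TestPoissonTail:
    def test_zero_observed(self):
        assert poisson_tail_p(0, 3.7) == 1.0

    def test_closed_form(self):
        assert poisson_tail_p(2, 1.0) == pytest.approx(1 - 2 * np.exp(-1), abs=1e-7)

    def test_zero_lambda(self):
        assert poisson_tail_p(3, 0.0) == 0.0

    def test_monotonicity(self):
        ks = [poisson_tail_p(k, 2.0) for k in range(8)]
        assert np.all(np.diff(ks) <= 0)
        lams = [poisson_tail_p(3, lam) for lam in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(lams) >= 0)


def _null_bundle(seed, n=400, with_effects=False):
    effects = []
    if with_effects:
        effects = [
            PlantedEffect("snp_probe_cis", snp_id="snp0001", probe_id="probe001", beta=0.9),
            PlantedEffect("probe_metab", probe_id="probe001", metabolite="M01", beta=0.7),
            PlantedEffect("snp_probe_metab_mediated", snp_id="snp0001",
                          probe_id="probe001", metabolite="M01", beta=0.63),
        ]
    cfg = SimConfig(n_discovery=n, n_replication=50, n_snps=60, n_probes=20,
                    n_metabolites=8, seed=seed, batch_shift_sd=0.0,
                    effects=effects)
    study = simulate_study(cfg)
    disc = study.discovery
    panel = prepare_panel(disc.metabolites, [])
    E = disc.expression_latent
    C = disc.covariates.select(["age", "sex"])
    return disc.genotypes, panel, E, C


class TestTriangleNull:
    def test_global_null_rarely_forms_triangles(self):
        G, panel, E, C = _null_bundle(seed=55)
        null = triangle_permutation_null(G, panel, E, C, None, None,
                                         n_perm=20, seed=5)
        assert null.counts.sum() <= 2
        assert null.lambda_hat == pytest.approx(null.counts.mean())

    def test_planted_mediation_beats_null(self):
        G, panel, E, C = _null_bundle(seed=56, n=700, with_effects=True)
        obs = discovery_triangle_analysis(G, panel, E, C, None, None)
        assert len(obs["triangles"]) >= 1
        null = triangle_permutation_null(G, panel, E, C, None, None,
                                         n_perm=20, seed=6)
        assert null.lambda_hat < 0.2

    def test_seed_determinism(self):
        G, panel, E, C = _null_bundle(seed=57)
        a = triangle_permutation_null(G, panel, E, C, None, None, n_perm=5, seed=7)
        b = triangle_permutation_null(G, panel, E, C, None, None, n_perm=7, seed=7)
        assert np.array_equal(a.counts, b.counts[:5])


class TestNetwork:
    def test_bookkeeping_and_roles(self):
        mq = pd.DataFrame([_assoc_row("rs1", "M1", "mqtl")])
        eq = pd.DataFrame([_assoc_row("rs1", "p1", "eqtl_cis")])
        em = pd.DataFrame([_assoc_row("p1", "M1", "expr_metab")])
        panel = make_panel(np.ones((3, 1)), names=["M1"])
        tri = build_triangles(mq, eq, em)
        nodes, edges = build_network(mq, eq, em, panel, tri)
        roles = dict(nodes)
        assert roles["rs1"] == "locus_with_triangle"
        assert roles["p1"] == "cis_gene"
        assert roles["M1"] == "raw_metabolite"
        assert len(edges) == len(mq) + len(eq) + len(em)
        assert all(0 <= e["explained_var"] < 1 for e in edges)

    def test_ratio_metabolite_role(self):
        from trimetaqtl.datatypes import MetaboliteDef, MetabolitePanel

        panel = MetabolitePanel(
            ["S1"], [MetaboliteDef("r", "ratio", ("a",), ("b",))],
            np.ones((1, 1)),
        )
        mq = pd.DataFrame([_assoc_row("rs1", "r", "mqtl")])
        nodes, _ = build_network(mq, pd.DataFrame(columns=mq.columns),
                                 pd.DataFrame(columns=mq.columns), panel, [])
        assert dict(nodes)["r"] == "metabolite_ratio"
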