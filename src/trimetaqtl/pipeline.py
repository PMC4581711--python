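"""End-to-end study pipeline on a synthetic or loaded cohort bundle.

Stage order mirrors the study design: metabolite preparation -> expression
preparation -> discovery mQTL scan -> permutation FDR -> LD pruning ->
proxy search -> replication -> eQTL mapping -> expression–metabolite
association -> association triangles (+ permutation null and Poisson tail)
-> causal inference -> network export.  A JSON manifest records the
configuration, per-stage child seeds and output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from trimetaqtl import io as tio
from trimetaqtl.assoc import genomic_lambda
from trimetaqtl.config import RunConfig
from trimetaqtl.datatypes import harmonize_samples
from trimetaqtl.expression import (
    adjust_batch,
    filter_expressed,
    flag_sample_outliers,
    quantile_normalize_log2,
    residualize_expression,
)
from trimetaqtl.integration import (
    TriangleNull,
    build_network,
    discovery_triangle_analysis,
    poisson_tail_p,
    triangle_permutation_null,
    triangles_to_frame,
)
from trimetaqtl.metabolites import prepare_panel
from trimetaqtl.mqtl import (
    attach_permutation_q,
    find_proxies,
    replicate,
)
from trimetaqtl.multiplicity import verify_bh_with_permutations
from trimetaqtl.simulate import SimConfig, StudyData, default_derived_defs, simulate_study

log = logging.getLogger(__name__)

#: covariate sets per analysis layer (replication omits the genetic PCs,
#: matching a replication cohort adjusted for relatedness instead)
MQTL_COVARIATES = ["age", "sex", "pc1", "pc2", "pc3"]
REPLICATION_COVARIATES = ["age", "sex"]
EXPRESSION_COVARIATES = ["age", "sex"]
EQTL_COVARIATES = ["pc1", "pc2", "pc3"]
EXPRMET_COVARIATES = ["age", "sex"]


def child_seed(master: int, k: int) -> int:
    return int((master * 1009 + k) % (2**31 - 1))


@dataclass
class PipelineResult:
    study: StudyData
    panel_discovery: object
    panel_replication: object
    expression_prepared: object
    qc_report: object
    mqtl_full: pd.DataFrame
    mqtl_top: pd.DataFrame
    leads: object
    proxies: pd.DataFrame
    replication: pd.DataFrame
    eqtl: pd.DataFrame
    exprmet: pd.DataFrame
    triangles: list
    triangles_exhaustive: list
    triangle_null: TriangleNull | None
    triangle_poisson_p: float | None
    causal: pd.DataFrame
    bh_permutation_report: dict | None
    genomic_lambda: float
    manifest: dict = field(default_factory=dict)


def prepare_expression(bundle, run_cfg: RunConfig):
    """Expression chain: detection filter, quantile-normalize + log2, sample
    outlier flags (samples dropped), batch adjustment (empirical Bayes),
    residualization on covariates + expression PCs."""

    E = filter_expressed(bundle.expression, bundle.detection_p)
    E = quantile_normalize_log2(E)
    n_expressed = (bundle.detection_p <= 0.05).sum(axis=1)
    report = flag_sample_outliers(E, qc_features=bundle.expression.qc_features,
                                  n_expressed=n_expressed)
    keep = [sid for sid, fl in zip(E.sample_ids, report.flags) if not fl]
    keep_idx = [i for i, fl in enumerate(report.flags) if not fl]
    E = E.subset_samples(keep)
    batch = np.asarray(bundle.batch_labels)[keep_idx]
    E = adjust_batch(E, batch, mode="eb")
    C_expr = bundle.covariates.subset_samples(keep).select(
        [c for c in EXPRESSION_COVARIATES if c in bundle.covariates.columns]
    )
    E = residualize_expression(E, C_expr, n_pcs=run_cfg.n_expression_pcs)
    return E, report


def run_all(
    run_cfg: RunConfig | None = None,
    sim_cfg: SimConfig | None = None,
    out_dir: str | Path | None = None,
    study: StudyData | None = None,
    run_triangle_null: bool = True,
    run_bh_check: bool = True,
) -> PipelineResult:
    """Execute the full pipeline and (optionally) write every stage file."""

    run_cfg = (run_cfg or RunConfig()).validate()
    sim_cfg = sim_cfg or SimConfig(seed=run_cfg.seed)
    t0 = time.time()
    stages: list[dict] = []

    def stage(name, t_start):
        stages.append({"stage": name, "seconds": round(time.time() - t_start, 3)})
        log.info("stage %-22s %6.1fs", name, time.time() - t_start)

    ts = time.time()
    if study is None:
        study = simulate_study(sim_cfg)
    disc, rep = study.discovery, study.replication
    stage("simulate", ts)

    # --- metabolite preparation -------------------------------------------
    ts = time.time()
    derived = [
        d for d in default_derived_defs()
        if all(c in disc.metabolites.names for c in d.numerator + d.denominator)
    ]
    panel_d = prepare_panel(disc.metabolites, derived,
                            run_cfg.lod_dichotomize_frac, run_cfg.outlier_sd)
    panel_r = prepare_panel(rep.metabolites, derived,
                            run_cfg.lod_dichotomize_frac, run_cfg.outlier_sd)
    stage("metabolite_prep", ts)

    # --- expression preparation -------------------------------------------
    ts = time.time()
    E_prep, qc_report = prepare_expression(disc, run_cfg)
    stage("expression_prep", ts)

    # --- discovery mQTL scan + permutation FDR ----------------------------
    ts = time.time()
    C_mqtl = disc.covariates.select(
        [c for c in MQTL_COVARIATES if c in disc.covariates.columns]
    )
    from trimetaqtl.mqtl import run_mqtl_scan

    full, top = run_mqtl_scan(disc.genotypes, panel_d, C_mqtl, run_cfg.discovery_p)
    full = attach_permutation_q(
        full, disc.genotypes, panel_d, C_mqtl,
        n_perm=run_cfg.n_perm_mqtl, seed=child_seed(run_cfg.seed, 1),
    )
    top = top.merge(full[["x_id", "y_id", "q"]], on=["x_id", "y_id"],
                    how="left", suffixes=("", "_perm"))
    top["q"] = top.pop("q_perm")
    lam = genomic_lambda(full["p"].dropna().to_numpy())
    stage("mqtl_scan", ts)

    # --- pruning, loci, proxies, replication ------------------------------
    ts = time.time()
    from trimetaqtl.mqtl import LeadSnpSet, assign_loci, prune_lead_snps

    if top.empty:
        log.warning("no discovery pair reached p < %g; replication skipped",
                    run_cfg.discovery_p)
        leads = LeadSnpSet(
            leads=pd.DataFrame(columns=["snp_id", "min_p", "best_metabolite",
                                        "chrom", "pos", "locus_id"]),
            r2_threshold=run_cfg.prune_r2,
        )
        proxies = pd.DataFrame(
            columns=["lead_snp_id", "proxy_snp_id", "r2", "distance", "proxy_info"]
        )
        replication = pd.DataFrame()
    else:
        leads = assign_loci(prune_lead_snps(top, disc.genotypes, run_cfg.prune_r2),
                            run_cfg.locus_merge_bp)
        proxies = find_proxies(
            sorted(top["x_id"].unique()), disc.genotypes, rep.genotypes,
            run_cfg.proxy_window_bp, run_cfg.proxy_r2, run_cfg.proxy_info_min,
        )
        C_rep = rep.covariates.select(
            [c for c in REPLICATION_COVARIATES if c in rep.covariates.columns]
        )
        replication = replicate(
            top, proxies, disc.genotypes, rep.genotypes, panel_r, C_rep,
            fdr=run_cfg.fdr, n_perm=run_cfg.n_perm_mqtl,
            seed=child_seed(run_cfg.seed, 2),
        )
    stage("replication", ts)

    # --- integrated triangle chain on the common sample set ---------------
    ts = time.time()
    G_c, panel_c, C_c, E_c, common = harmonize_samples(
        disc.genotypes, panel_d, disc.covariates, E_prep
    )
    C_mqtl_c = C_c.select([c for c in MQTL_COVARIATES if c in C_c.columns])
    C_eqtl_c = C_c.select([c for c in EQTL_COVARIATES if c in C_c.columns])
    C_em_c = C_c.select([c for c in EXPRMET_COVARIATES if c in C_c.columns])
    chain = discovery_triangle_analysis(
        G_c, panel_c, E_c, C_mqtl_c, C_eqtl_c, C_em_c,
        discovery_p=run_cfg.discovery_p, fdr=run_cfg.fdr,
        prune_r2=run_cfg.prune_r2, cis_window_bp=run_cfg.cis_window_bp,
        locus_merge_bp=run_cfg.locus_merge_bp,
    )
    eqtl, exprmet, triangles = chain["eqtl"], chain["exprmet"], chain["triangles"]
    chain_ex = discovery_triangle_analysis(
        G_c, panel_c, E_c, C_mqtl_c, C_eqtl_c, C_em_c,
        discovery_p=run_cfg.discovery_p, fdr=run_cfg.fdr,
        prune_r2=run_cfg.prune_r2, cis_window_bp=run_cfg.cis_window_bp,
        locus_merge_bp=run_cfg.locus_merge_bp, mode="exhaustive",
    )
    triangles_ex = chain_ex["triangles"]
    stage("integration", ts)

    # --- triangle permutation null ----------------------------------------
    tri_null, tri_p = None, None
    if run_triangle_null:
        ts = time.time()
        tri_null = triangle_permutation_null(
            G_c, panel_c, E_c, C_mqtl_c, C_eqtl_c, C_em_c,
            n_perm=run_cfg.n_perm_triangle, seed=child_seed(run_cfg.seed, 3),
            reprune=run_cfg.reprune_in_triangle_null, leads=chain["leads"],
            discovery_p=run_cfg.discovery_p, fdr=run_cfg.fdr,
            prune_r2=run_cfg.prune_r2, cis_window_bp=run_cfg.cis_window_bp,
            locus_merge_bp=run_cfg.locus_merge_bp,
        )
        tri_p = poisson_tail_p(len(triangles), tri_null.lambda_hat)
        stage("triangle_null", ts)

    # --- BH confirmation for the eQTL layer --------------------------------
    bh_report = None
    if run_bh_check and chain["leads"] is not None:
        ts = time.time()
        doses = np.column_stack([G_c.dose(s) for s in chain["leads"].snp_ids])
        cis_mask = (
            eqtl.pivot_table(index="x_id", columns="y_id", values="layer",
                             aggfunc="first", sort=False)
            .reindex(index=chain["leads"].snp_ids, columns=E_c.probe_ids)
            .eq("eqtl_cis").to_numpy()
        )
        bh_report = verify_bh_with_permutations(
            doses, E_c.values, C_eqtl_c, cis_mask, alpha=run_cfg.fdr,
            n_perm=run_cfg.n_perm_eqtl, seed=child_seed(run_cfg.seed, 4),
        )
        stage("bh_confirmation", ts)

    # --- causal inference ---------------------------------------------------
    ts = time.time()
    C_causal = C_c.select([c for c in MQTL_COVARIATES if c in C_c.columns])
    from trimetaqtl.causal import summarize_causal

    causal = summarize_causal(triangles, G_c, E_c, panel_c, C_causal)
    stage("causal", ts)

    # --- network ------------------------------------------------------------
    ts = time.time()
    mqtl_sig = chain["top"][chain["top"]["x_id"].isin(
        chain["leads"].snp_ids if chain["leads"] is not None else []
    )]
    nodes, edges = build_network(
        mqtl_sig, eqtl[eqtl.get("significant", pd.Series(dtype=bool)) == True]  # noqa: E712
        if not eqtl.empty else eqtl,
        exprmet[exprmet["significant"]] if not exprmet.empty else exprmet,
        panel_c, triangles,
    )
    stage("network", ts)

    manifest = {
        "software": "trimetaqtl 0.1.0",
        "config": dataclasses.asdict(run_cfg),
        "sim_config": {
            k: v for k, v in dataclasses.asdict(sim_cfg).items() if k != "effects"
        },
        "seeds": {f"stage_{k}": child_seed(run_cfg.seed, k) for k in range(1, 5)},
        "stages": stages,
        "total_seconds": round(time.time() - t0, 3),
    }

    result = PipelineResult(
        study=study, panel_discovery=panel_d, panel_replication=panel_r,
        expression_prepared=E_prep, qc_report=qc_report,
        mqtl_full=full, mqtl_top=top, leads=leads, proxies=proxies,
        replication=replication, eqtl=eqtl, exprmet=exprmet,
        triangles=triangles, triangles_exhaustive=triangles_ex,
        triangle_null=tri_null, triangle_poisson_p=tri_p, causal=causal,
        bh_permutation_report=bh_report, genomic_lambda=lam, manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, nodes, edges, Path(out_dir))
    result.manifest["network_nodes"] = len(nodes)
    result.manifest["network_edges"] = len(edges)
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, nodes, edges, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    disc, rep = result.study.discovery, result.study.replication
    tio.write_genotypes(disc.genotypes, out_dir / "genotypes_discovery.tsv",
                        out_dir / "snp_annotation.tsv")
    tio.write_genotypes(rep.genotypes, out_dir / "genotypes_replication.tsv")
    tio.write_expression(result.expression_prepared,
                         out_dir / "expression_prepared.tsv",
                         out_dir / "probe_annotation.tsv")
    tio.write_metabolites(result.panel_discovery,
                          out_dir / "metabolites_prepared_discovery.tsv",
                          out_dir / "metabolite_defs.tsv")
    tio.write_covariates(disc.covariates, out_dir / "covariates_discovery.tsv")
    result.study.truth.to_frame().to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    frames = {
        "mqtl_full_scan.tsv": result.mqtl_full,
        "mqtl_top.tsv": result.mqtl_top,
        "lead_snps.tsv": result.leads.leads if result.leads is not None else pd.DataFrame(),
        "proxies.tsv": result.proxies,
        "replication.tsv": result.replication,
        "eqtl.tsv": result.eqtl,
        "expr_metab.tsv": result.exprmet,
        "triangles.tsv": triangles_to_frame(result.triangles),
        "triangles_exhaustive.tsv": triangles_to_frame(result.triangles_exhaustive),
        "causal.tsv": result.causal,
    }
    for name, frame in frames.items():
        frame.to_csv(out_dir / name, sep="\t", index=False, na_rep="NA",
                     float_format="%.12g")
    if result.triangle_null is not None:
        pd.DataFrame({"permutation": np.arange(result.triangle_null.n_perm),
                      "n_triangles": result.triangle_null.counts}).to_csv(
            out_dir / "triangle_null.tsv", sep="\t", index=False)
    tio.write_network(nodes, edges, out_dir / "network.graphml", "graphml")
    digests = {p.name: _sha256(p) for p in sorted(out_dir.iterdir()) if p.is_file()
               and p.name != "manifest.json"}
    result.manifest["file_digests"] = digests
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
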