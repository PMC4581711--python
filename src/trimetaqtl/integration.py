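"""eQTL mapping, expression–metabolite association, association-triangle
discovery with a permutation/Poisson null, and network assembly.

An association triangle is a SNP significantly associated with both an
expression probe and a metabolite, where the probe is also associated with
the metabolite.  The expected triangle count under the null is estimated by
re-running the whole discovery analysis on datasets in which the expression
block and the metabolite block are independently re-assigned to the
genotypes; the observed count is compared with a Poisson tail probability at
the permutation mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trimetaqtl.assoc import scan_ols
from trimetaqtl.datatypes import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    MetabolitePanel,
    ProbeRecord,
    SnpRecord,
    TriangleRecord,
    frame_to_associations,
)
from trimetaqtl.mqtl import LeadSnpSet, assign_loci, prune_lead_snps, run_mqtl_scan, scan_to_frame
from trimetaqtl.multiplicity import bh_qvalues, bh_threshold

log = logging.getLogger(__name__)


def classify_cis_trans(
    snp: SnpRecord, probe: ProbeRecord, window_bp: int = 1_000_000
) -> str:
    """cis iff same chromosome and |SNP pos - probe center| <= window (inclusive)."""

    if snp.chrom in ("", "NA") or probe.chrom in ("", "NA"):
        raise ValueError("missing coordinates for cis/trans classification")
    if snp.chrom == probe.chrom and abs(snp.pos - probe.center) <= window_bp:
        return "cis"
    return "trans"


def run_eqtl_scan(
    leads: LeadSnpSet | list[str],
    G: GenotypeMatrix,
    E_prepared: ExpressionMatrix,
    C_genetic_pcs: CovariateTable | None = None,
    fdr: float = 0.05,
    cis_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """eQTL scan of lead SNPs against all prepared probes.

    Records are labelled cis/trans by the 1 Mb rule and significance is
    decided by separate Benjamini–Hochberg thresholds within each layer at
    FDR ``fdr``; the ``significant`` column carries the call.
    """

    snp_ids = leads.snp_ids if isinstance(leads, LeadSnpSet) else list(leads)
    doses = np.column_stack([G.dose(s) for s in snp_ids])
    scan = scan_ols(E_prepared.values, doses, C_genetic_pcs)
    frame = scan_to_frame(scan, snp_ids, E_prepared.probe_ids, "eqtl_cis")
    labels = [
        classify_cis_trans(G.snp(x), E_prepared.probe(y), cis_window_bp)
        for x, y in zip(frame["x_id"], frame["y_id"])
    ]
    frame["layer"] = ["eqtl_cis" if lab == "cis" else "eqtl_trans" for lab in labels]
    cis = frame["layer"] == "eqtl_cis"
    p = frame["p"].to_numpy()
    thr_cis = bh_threshold(p[cis.to_numpy()], fdr)
    thr_trans = bh_threshold(p[~cis.to_numpy()], fdr)
    frame.loc[cis, "q"] = bh_qvalues(p[cis.to_numpy()])
    frame.loc[~cis, "q"] = bh_qvalues(p[~cis.to_numpy()])
    frame["significant"] = np.where(
        cis, (p <= thr_cis) & (thr_cis > 0), (p <= thr_trans) & (thr_trans > 0)
    )
    frame.attrs["thresholds"] = {"cis": thr_cis, "trans": thr_trans}
    return frame


def run_expr_metab_scan(
    probe_ids: list[str],
    E_prepared: ExpressionMatrix,
    panel: MetabolitePanel,
    C: CovariateTable | None = None,
    fdr: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Expression–metabolite associations over the triangle candidate grid.

    ``pairs`` restricts the grid to specific (probe, metabolite)
    combinations (eQTL probes x metabolites associated at the corresponding
    SNP); BH q-values at FDR ``fdr`` are computed within exactly this grid.
    """

    if not probe_ids:
        return pd.DataFrame(columns=["x_id", "y_id", "layer", "beta", "se", "t", "p",
                                     "q", "n", "df", "explained_var", "significant"])
    expr = np.column_stack([E_prepared.expression(p) for p in probe_ids])
    scan = scan_ols(panel.values, expr, C)
    frame = scan_to_frame(scan, probe_ids, panel.names, "expr_metab")
    if pairs is not None:
        want = set(pairs)
        frame = frame[[
            (x, y) in want for x, y in zip(frame["x_id"], frame["y_id"])
        ]].reset_index(drop=True)
    p = frame["p"].to_numpy()
    thr = bh_threshold(p, fdr)
    frame["q"] = bh_qvalues(p)
    frame["significant"] = (p <= thr) & (thr > 0)
    frame.attrs["threshold"] = thr
    return frame


# ---------------------------------------------------------------------------
# triangles
# ---------------------------------------------------------------------------

def build_triangles(
    mqtl_sig: pd.DataFrame,
    eqtl_sig: pd.DataFrame,
    exprmet_sig: pd.DataFrame,
    leads: LeadSnpSet | None = None,
    mode: str = "strict",
) -> list[TriangleRecord]:
    """Close significant SNP–probe–metabolite triples into triangles.

    ``strict`` follows the study recipe: per locus, the top SNP (minimal
    mQTL p), its best-associated metabolite and that SNP's significant eQTL
    probes; a triangle forms for each probe also significantly associated
    with the metabolite.  ``exhaustive`` enumerates every significant
    closure (for the network view).
    """

    if mode not in ("strict", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    if mqtl_sig.empty or eqtl_sig.empty or exprmet_sig.empty:
        return []
    eqtl_idx = {(r.x_id, r.y_id): r for r in eqtl_sig.itertuples(index=False)}
    em_idx = {(r.x_id, r.y_id): r for r in exprmet_sig.itertuples(index=False)}

    def edge_record(row, layer):
        frame = pd.DataFrame([row._asdict()])
        frame["layer"] = layer
        cols = ["x_id", "y_id", "layer", "beta", "se", "t", "p", "q", "n",
                "explained_var"]
        return frame_to_associations(frame[cols])[0]

    candidates: list[tuple] = []  # (mqtl_row, snp, metab)
    if mode == "strict":
        frame = mqtl_sig.copy()
        if leads is not None and "locus_id" in getattr(leads, "leads", pd.DataFrame()):
            locus_of = dict(zip(leads.leads["snp_id"], leads.leads["locus_id"]))
            frame = frame[frame["x_id"].isin(locus_of)].copy()
            frame["locus"] = frame["x_id"].map(locus_of)
        else:
            frame["locus"] = frame["x_id"]
        for _, grp in frame.groupby("locus"):
            best = grp.loc[grp["p"].idxmin()]
            candidates.append((best, best["x_id"], best["y_id"]))
    else:
        for row in mqtl_sig.itertuples(index=False):
            candidates.append((pd.Series(row._asdict()), row.x_id, row.y_id))

    triangles: list[TriangleRecord] = []
    for mrow, snp, metab in candidates:
        for (esnp, probe), erow in eqtl_idx.items():
            if esnp != snp:
                continue
            emrow = em_idx.get((probe, metab))
            if emrow is None:
                continue
            mqtl_rec = frame_to_associations(
                pd.DataFrame([{**{c: mrow[c] for c in
                                  ["x_id", "y_id", "layer", "beta", "se", "t", "p",
                                   "q", "n", "explained_var"]}}])
            )[0]
            triangles.append(
                TriangleRecord(
                    snp_id=snp, probe_id=probe, metabolite=metab,
                    assoc_mqtl=mqtl_rec,
                    assoc_eqtl=edge_record(erow, erow.layer),
                    assoc_expr_metab=edge_record(emrow, "expr_metab"),
                    cis_or_trans="cis" if erow.layer == "eqtl_cis" else "trans",
                )
            )
    return triangles


def triangles_to_frame(triangles: list[TriangleRecord]) -> pd.DataFrame:
    rows = []
    for t in triangles:
        rows.append(
            {
                "snp_id": t.snp_id, "probe_id": t.probe_id, "metabolite": t.metabolite,
                "cis_or_trans": t.cis_or_trans,
                "beta_mqtl": t.assoc_mqtl.beta, "se_mqtl": t.assoc_mqtl.se,
                "p_mqtl": t.assoc_mqtl.p, "r2_mqtl": t.assoc_mqtl.explained_var,
                "beta_eqtl": t.assoc_eqtl.beta, "se_eqtl": t.assoc_eqtl.se,
                "p_eqtl": t.assoc_eqtl.p, "r2_eqtl": t.assoc_eqtl.explained_var,
                "beta_exprmet": t.assoc_expr_metab.beta,
                "se_exprmet": t.assoc_expr_metab.se,
                "p_exprmet": t.assoc_expr_metab.p,
                "r2_exprmet": t.assoc_expr_metab.explained_var,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TriangleNull:
    """Triangle counts under block-permutation of the omics layers."""

    n_perm: int
    counts: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("negative triangle count")

    @property
    def lambda_hat(self) -> float:
        return float(self.counts.mean()) if self.counts.size else 0.0


def discovery_triangle_analysis(
    G: GenotypeMatrix,
    panel: MetabolitePanel,
    E_prepared: ExpressionMatrix,
    C_mqtl: CovariateTable | None,
    C_eqtl: CovariateTable | None,
    C_exprmet: CovariateTable | None,
    discovery_p: float = 1.0e-7,
    fdr: float = 0.05,
    prune_r2: float = 0.3,
    cis_window_bp: int = 1_000_000,
    locus_merge_bp: int = 1_000_000,
    leads: LeadSnpSet | None = None,
    mode: str = "strict",
) -> dict:
    """One pass of the triangle discovery chain with fixed thresholds.

    scan -> (prune leads unless frozen ``leads`` are supplied) -> eQTL ->
    expression–metabolite grid -> triangles.  mQTL significance inside the
    chain is the discovery cut-off; eQTL and expression–metabolite layers use
    their BH procedures at ``fdr``.
    """

    full, top = run_mqtl_scan(G, panel, C_mqtl, discovery_p)
    if top.empty:
        return {"top": top, "leads": None, "eqtl": pd.DataFrame(),
                "exprmet": pd.DataFrame(), "triangles": []}
    if leads is None:
        leads = assign_loci(prune_lead_snps(top, G, prune_r2), locus_merge_bp)
    mqtl_sig = top[top["x_id"].isin(leads.snp_ids)].reset_index(drop=True)
    eqtl = run_eqtl_scan(leads, G, E_prepared, C_eqtl, fdr, cis_window_bp)
    eqtl_sig = eqtl[eqtl["significant"]].reset_index(drop=True)
    if eqtl_sig.empty:
        return {"top": top, "leads": leads, "eqtl": eqtl,
                "exprmet": pd.DataFrame(), "triangles": []}
    # candidate grid: eQTL probes x metabolites significant at that SNP
    pairs = sorted(
        {
            (erow.y_id, mrow.y_id)
            for erow in eqtl_sig.itertuples(index=False)
            for mrow in mqtl_sig.itertuples(index=False)
            if mrow.x_id == erow.x_id
        }
    )
    probe_ids = sorted({p for p, _ in pairs})
    exprmet = run_expr_metab_scan(probe_ids, E_prepared, panel, C_exprmet, fdr, pairs)
    exprmet_sig = exprmet[exprmet["significant"]].reset_index(drop=True) \
        if not exprmet.empty else exprmet
    triangles = build_triangles(mqtl_sig, eqtl_sig, exprmet_sig, leads, mode=mode)
    return {"top": top, "leads": leads, "eqtl": eqtl, "exprmet": exprmet,
            "triangles": triangles}


def triangle_permutation_null(
    G: GenotypeMatrix,
    panel: MetabolitePanel,
    E_prepared: ExpressionMatrix,
    C_mqtl: CovariateTable | None,
    C_eqtl: CovariateTable | None,
    C_exprmet: CovariateTable | None,
    n_perm: int = 100,
    seed: int = 0,
    reprune: bool = True,
    leads: LeadSnpSet | None = None,
    **thresholds,
) -> TriangleNull:
    """Null distribution of triangle counts.

    Per permutation, the sample assignment of the expression block and
    (independently) the metabolite block are shuffled against the genotypes
    and the entire chain reruns with identical thresholds.  ``reprune=False``
    freezes the observed lead set instead of re-pruning per permutation.
    """

    rng = np.random.default_rng(seed)
    n = len(G.sample_ids)
    counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        pe = rng.permutation(n)
        pm = rng.permutation(n)
        E_perm = ExpressionMatrix(
            list(E_prepared.sample_ids), E_prepared.probes, E_prepared.values[pe]
        )
        panel_perm = panel.replace(
            sample_ids=list(panel.sample_ids),
            values=panel.values[pm],
            below_lod=panel.below_lod[pm],
        )
        try:
            res = discovery_triangle_analysis(
                G, panel_perm, E_perm, C_mqtl, C_eqtl, C_exprmet,
                leads=None if reprune else leads, **thresholds,
            )
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"triangle null failed in permutation {b}") from exc
        counts[b] = len(res["triangles"])
    return TriangleNull(n_perm=n_perm, counts=counts, seed=seed)


def poisson_tail_p(k_observed: int, lambda_hat: float) -> float:
    """P(X >= k) for X ~ Poisson(lambda), computed stably."""

    if k_observed < 0:
        raise ValueError("k must be >= 0")
    if lambda_hat < 0:
        raise ValueError("lambda must be >= 0")
    if k_observed == 0:
        return 1.0
    if lambda_hat == 0:
        return 0.0
    return float(stats.poisson.sf(k_observed - 1, lambda_hat))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def build_network(
    mqtl_sig: pd.DataFrame,
    eqtl_sig: pd.DataFrame,
    exprmet_sig: pd.DataFrame,
    panel: MetabolitePanel,
    triangles: list[TriangleRecord] | None = None,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """Typed nodes and explained-variance-weighted edges for export.

    Node roles: locus / locus_with_triangle (lead SNPs), cis_gene /
    trans_gene (probes by their best eQTL layer), raw_metabolite /
    metabolite_ratio (by panel definition kind).
    """

    tri_snps = {t.snp_id for t in (triangles or [])}
    nodes: dict[str, str] = {}
    edges: list[dict] = []

    def add_edge(u, v, layer, ev):
        edges.append({"u": u, "v": v, "layer": layer, "explained_var": float(ev)})

    for row in mqtl_sig.itertuples(index=False):
        nodes[row.x_id] = "locus_with_triangle" if row.x_id in tri_snps else "locus"
    for row in eqtl_sig.itertuples(index=False):
        nodes.setdefault(row.x_id, "locus_with_triangle" if row.x_id in tri_snps else "locus")
        role = "cis_gene" if row.layer == "eqtl_cis" else "trans_gene"
        if nodes.get(row.y_id) != "cis_gene":  # cis takes precedence
            nodes[row.y_id] = role
    for frame in (mqtl_sig, exprmet_sig):
        for row in frame.itertuples(index=False):
            if row.y_id in panel.names:
                kind = panel.definition(row.y_id).kind
                nodes[row.y_id] = (
                    "metabolite_ratio" if kind == "ratio" else "raw_metabolite"
                )
    for row in exprmet_sig.itertuples(index=False):
        nodes.setdefault(row.x_id, "cis_gene")

    seen = set()
    for frame in (mqtl_sig, eqtl_sig, exprmet_sig):
        for row in frame.itertuples(index=False):
            key = (row.x_id, row.y_id, row.layer)
            if key in seen:
                continue
            seen.add(key)
            add_edge(row.x_id, row.y_id, row.layer, row.explained_var)
    return list(nodes.items()), edges
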