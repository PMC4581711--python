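"""Discovery mQTL scan, LD pruning, locus assignment, proxy search and
direction-consistent replication.

The two-stage design: a liberal discovery cut-off (p < 1e-7) defines the
top list; lead SNPs are greedily pruned at LD r^2 < 0.3 ordered by minimal
p across metabolites; replication pairs each top SNP with its best proxy
(+/-50 kb, r^2 > 0.8 computed in the discovery cohort, imputation info > 0.3
in the replication panel) and declares a pair replicated when the
orientation-corrected effect direction matches discovery and the empirical
permutation q-value is <= 5%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trimetaqtl.assoc import scan_ols
from trimetaqtl.datatypes import CovariateTable, GenotypeMatrix, MetabolitePanel
from trimetaqtl.multiplicity import (
    empirical_qvalues,
    permute_phenotype_links,
    scan_statistics,
)

log = logging.getLogger(__name__)

SCAN_COLUMNS = ["x_id", "y_id", "layer", "beta", "se", "t", "p", "q", "n",
                "df", "explained_var"]


def scan_to_frame(
    scan: dict[str, np.ndarray], x_ids, y_ids, layer: str
) -> pd.DataFrame:
    """Flatten a (n_x, n_y) scan into one association row per pair."""

    m, q = scan["beta"].shape
    xi, yi = np.repeat(np.arange(m), q), np.tile(np.arange(q), m)
    frame = pd.DataFrame(
        {
            "x_id": np.asarray(x_ids, dtype=object)[xi],
            "y_id": np.asarray(y_ids, dtype=object)[yi],
            "layer": layer,
            "beta": scan["beta"].ravel(),
            "se": scan["se"].ravel(),
            "t": scan["t"].ravel(),
            "p": scan["p"].ravel(),
            "q": np.nan,
            "n": scan["n"].ravel(),
            "df": scan["df"].ravel(),
            "explained_var": scan["explained_var"].ravel(),
        }
    )
    return frame[SCAN_COLUMNS]


def run_mqtl_scan(
    G: GenotypeMatrix,
    panel: MetabolitePanel,
    C: CovariateTable | None,
    p_report: float = 1.0e-7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full (SNP x metabolite) covariate-adjusted scan.

    Returns the complete p table (kept for the permutation FDR) and the top
    list of pairs with p < ``p_report``.
    """

    scan = scan_ols(panel.values, G.doses, C)
    full = scan_to_frame(scan, G.snp_ids, panel.names, "mqtl")
    top = full[full["p"] < p_report].sort_values("p").reset_index(drop=True)
    return full, top


def attach_permutation_q(
    full: pd.DataFrame,
    G: GenotypeMatrix,
    panel: MetabolitePanel,
    C: CovariateTable | None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical q-values for the discovery scan (-log10 p statistic) from
    permuting the metabolite block against the genotypes."""

    null = permute_phenotype_links(
        G.doses, panel.values, C, n_perm=n_perm,
        statistic_kind="neglog10p", seed=seed, layer="mqtl",
    )
    out = full.copy()
    out["q"] = empirical_qvalues(-np.log10(out["p"].to_numpy()), null)
    return out


# ---------------------------------------------------------------------------
# LD and pruning
# ---------------------------------------------------------------------------

def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of the two dose vectors on complete cases."""

    a, b = G.dose(snp_a), G.dose(snp_b)
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError(f"monomorphic SNP among {snp_a!r}, {snp_b!r}")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LeadSnpSet:
    """Pruned lead SNPs ordered by ascending discovery p."""

    leads: pd.DataFrame  # snp_id, chrom, pos, min_p, best_metabolite [, locus_id]
    r2_threshold: float
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.leads["snp_id"])


def prune_lead_snps(
    top: pd.DataFrame, G: GenotypeMatrix, r2_max: float = 0.3
) -> LeadSnpSet:
    """Greedy LD pruning of the top list.

    Each SNP is ranked by its minimal p across metabolites; the best SNP is
    retained and every remaining SNP with r^2 >= ``r2_max`` to a retained
    SNP is discarded, repeatedly.
    """

    if top.empty:
        raise ValueError("top list is empty")
    per_snp = (
        top.sort_values("p").groupby("x_id", sort=False)
        .agg(min_p=("p", "min"), best_metabolite=("y_id", "first"))
        .reset_index().rename(columns={"x_id": "snp_id"})
        .sort_values(["min_p", "snp_id"], kind="stable").reset_index(drop=True)
    )
    candidates = list(per_snp["snp_id"])
    doses = {s: G.dose(s) for s in candidates}
    retained: list[str] = []
    for snp in candidates:
        x = doses[snp]
        keep = True
        for r in retained:
            y = doses[r]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            if np.corrcoef(x, y)[0, 1] ** 2 >= r2_max:
                keep = False
                break
        if keep:
            retained.append(snp)
    leads = per_snp[per_snp["snp_id"].isin(retained)].reset_index(drop=True)
    leads["chrom"] = [G.snp(s).chrom for s in leads["snp_id"]]
    leads["pos"] = [G.snp(s).pos for s in leads["snp_id"]]
    records = top[top["x_id"].isin(retained)].reset_index(drop=True)
    return LeadSnpSet(leads=leads, r2_threshold=r2_max, records=records)


def assign_loci(leads: LeadSnpSet, merge_bp: int = 1_000_000) -> LeadSnpSet:
    """Single-linkage merge of lead SNPs within ``merge_bp`` on a chromosome
    into loci; locus ids ordered by genome position."""

    frame = leads.leads.copy()
    order = frame.sort_values(["chrom", "pos"],
                              key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s)
    locus_of: dict[str, int] = {}
    locus = -1
    prev_chrom, prev_pos = None, None
    for row in order.itertuples(index=False):
        if row.chrom != prev_chrom or row.pos - prev_pos > merge_bp:
            locus += 1
        locus_of[row.snp_id] = locus
        prev_chrom, prev_pos = row.chrom, row.pos
    frame["locus_id"] = [f"locus{locus_of[s] + 1:03d}" for s in frame["snp_id"]]
    return LeadSnpSet(leads=frame, r2_threshold=leads.r2_threshold, records=leads.records)


def _chrom_key(chrom):
    try:
        return int(chrom)
    except (TypeError, ValueError):
        return 10_000 + hash(chrom) % 1000


# ---------------------------------------------------------------------------
# proxies and replication
# ---------------------------------------------------------------------------

def find_proxies(
    lead_snp_ids,
    G_discovery: GenotypeMatrix,
    G_replication: GenotypeMatrix,
    window_bp: int = 50_000,
    r2_min: float = 0.8,
    info_min: float = 0.3,
) -> pd.DataFrame:
    """Best qualifying replication proxy per lead SNP.

    Candidates are replication-panel SNPs within +/-``window_bp`` of the lead
    with imputation info > ``info_min``; LD is computed in the discovery
    cohort (where lead and candidate both exist).  Leads without a proxy of
    r^2 > ``r2_min`` are reported unreplicable (absent from the result).
    """

    rep_by_id = {s.snp_id: s for s in G_replication.snps}
    disc_ids = set(G_discovery.snp_ids)
    rows = []
    for lead in lead_snp_ids:
        lead_rec = G_discovery.snp(lead)
        best = None
        for cand_id, cand in rep_by_id.items():
            if cand.chrom != lead_rec.chrom or abs(cand.pos - lead_rec.pos) > window_bp:
                continue
            if cand.info <= info_min or cand_id not in disc_ids:
                continue
            r2 = ld_r2(G_discovery, lead, cand_id)
            if r2 > r2_min and (best is None or r2 > best[1]):
                best = (cand_id, r2, abs(cand.pos - lead_rec.pos), cand.info)
        if best is not None:
            rows.append(
                {"lead_snp_id": lead, "proxy_snp_id": best[0], "r2": best[1],
                 "distance": best[2], "proxy_info": best[3]}
            )
        else:
            log.info("no qualifying proxy for lead %s", lead)
    return pd.DataFrame(
        rows, columns=["lead_snp_id", "proxy_snp_id", "r2", "distance", "proxy_info"]
    )


def replicate(
    top_pairs: pd.DataFrame,
    proxies: pd.DataFrame,
    G_discovery: GenotypeMatrix,
    G_replication: GenotypeMatrix,
    panel_replication: MetabolitePanel,
    C_replication: CovariateTable | None,
    fdr: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    orient_min_r: float = 0.05,
) -> pd.DataFrame:
    """Replicate discovery (SNP, metabolite) pairs through their proxies.

    Each pair is retested in the replication cohort with the proxy dose.
    Allele orientation is the sign of the discovery dose correlation between
    lead and proxy; ``direction_consistent`` requires
    sign(beta_rep * orientation) == sign(beta_disc).  Empirical q-values come
    from permuting the replication metabolite block, with the statistic the
    signed z oriented by the discovery direction (one-sided).  A pair is
    ``replicated`` when direction-consistent and q <= ``fdr``.
    """

    proxy_of = dict(zip(proxies["lead_snp_id"], proxies["proxy_snp_id"]))
    pairs, orients, drops = [], [], 0
    for row in top_pairs.itertuples(index=False):
        proxy = proxy_of.get(row.x_id)
        if proxy is None:
            continue
        if row.y_id not in panel_replication.names:
            continue
        r = np.corrcoef(G_discovery.dose(row.x_id), G_discovery.dose(proxy))[0, 1]
        if abs(r) < orient_min_r:
            log.warning("pair %s/%s unorientable (|r|=%.3f), excluded",
                        row.x_id, row.y_id, abs(r))
            drops += 1
            continue
        pairs.append((row.x_id, proxy, row.y_id, float(row.beta), float(np.sign(r))))
        orients.append(np.sign(r))
    if not pairs:
        return pd.DataFrame(
            columns=["snp_id", "proxy_snp_id", "metabolite", "beta_disc", "beta_rep",
                     "se_rep", "p_rep", "n_rep", "orientation", "statistic", "q",
                     "direction_consistent", "replicated"]
        )

    proxy_ids = sorted({p[1] for p in pairs})
    metab_names = sorted({p[2] for p in pairs})
    doses = np.column_stack([G_replication.dose(s) for s in proxy_ids])
    yvals = np.column_stack([panel_replication.column(m) for m in metab_names])
    xi = {s: j for j, s in enumerate(proxy_ids)}
    yi = {m: j for j, m in enumerate(metab_names)}
    pair_idx = np.asarray([[xi[p[1]], yi[p[2]]] for p in pairs])
    # orientation matrix: discovery direction x allele orientation per tested cell
    orient = np.ones((len(proxy_ids), len(metab_names)))
    for (lead, proxy, metab, beta_disc, ori) in pairs:
        orient[xi[proxy], yi[metab]] = np.sign(beta_disc) * ori

    scan = scan_ols(yvals, doses, C_replication)
    stat = scan_statistics(scan, "signed_z", orient)[pair_idx[:, 0], pair_idx[:, 1]]
    null = permute_phenotype_links(
        doses, yvals, C_replication, n_perm=n_perm, statistic_kind="signed_z",
        seed=seed, pairs=pair_idx, orient=orient, layer="mqtl",
    )
    q = empirical_qvalues(stat, null)

    rows = []
    for k, (lead, proxy, metab, beta_disc, ori) in enumerate(pairs):
        i, j = pair_idx[k]
        beta_rep = scan["beta"][i, j]
        consistent = bool(np.sign(beta_rep * ori) == np.sign(beta_disc)) \
            if np.isfinite(beta_rep) else False
        rows.append(
            {
                "snp_id": lead, "proxy_snp_id": proxy, "metabolite": metab,
                "beta_disc": beta_disc, "beta_rep": beta_rep,
                "se_rep": scan["se"][i, j], "p_rep": scan["p"][i, j],
                "n_rep": scan["n"][i, j], "orientation": ori,
                "statistic": stat[k], "q": q[k],
                "direction_consistent": consistent,
                "replicated": consistent and np.isfinite(q[k]) and q[k] <= fdr,
            }
        )
    return pd.DataFrame(rows)
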