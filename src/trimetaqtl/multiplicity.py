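"""Multiple-testing control for correlated association grids.

Two routes, matching the two stages of the study design:

* an empirical q-value estimator against a permutation null in which the
  phenotype block as a whole is re-assigned to the genotypes (preserving LD
  among SNPs and correlation among traits) — used for the mQTL discovery /
  replication FDR;
* layer-wise Benjamini–Hochberg control (separate cis and trans thresholds)
  for eQTL and expression–metabolite grids, with an optional permutation
  check of the realized FDR at the BH thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from trimetaqtl.assoc import scan_ols

STATISTIC_KINDS = ("neglog10p", "signed_z")


@dataclass
class PermutationNull:
    """Null statistics from permuting phenotype-to-genotype sample links."""

    layer: str
    n_perm: int
    statistic_kind: str
    null_stats: np.ndarray  # (n_perm, n_tests)
    seed: int

    def __post_init__(self) -> None:
        self.null_stats = np.asarray(self.null_stats, dtype=float)
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.statistic_kind not in STATISTIC_KINDS:
            raise ValueError(f"unknown statistic kind {self.statistic_kind!r}")
        if self.null_stats.shape[0] != self.n_perm:
            raise ValueError("null_stats first axis must equal n_perm")


def scan_statistics(
    scan: dict[str, np.ndarray],
    statistic_kind: str,
    orient: np.ndarray | None = None,
) -> np.ndarray:
    """Turn a scan result into the FDR test statistic.

    ``neglog10p``: -log10(p), two-sided.  ``signed_z``: the signed normal
    quantile equivalent of the two-sided p, optionally multiplied by an
    orientation sign array (used for direction-aware replication, where the
    discovery direction defines the one-sided alternative).
    """

    if statistic_kind == "neglog10p":
        return -np.log10(scan["p"])
    if statistic_kind == "signed_z":
        z = stats.norm.isf(np.clip(scan["p"] / 2.0, np.finfo(float).tiny, 1.0))
        z = z * np.sign(scan["t"])
        if orient is not None:
            z = z * orient
        return z
    raise ValueError(f"unknown statistic kind {statistic_kind!r}")


def permute_phenotype_links(
    doses: np.ndarray,
    Y: np.ndarray,
    C,
    n_perm: int = 1000,
    statistic_kind: str = "neglog10p",
    seed: int = 0,
    pairs: np.ndarray | None = None,
    orient: np.ndarray | None = None,
    layer: str = "mqtl",
) -> PermutationNull:
    """Permutation null for the (SNPs x traits) association grid.

    In each permutation the sample index of the whole trait block ``Y`` is
    shuffled relative to the genotypes; covariates stay attached to the
    genotypes, so the null is covariate-adjusted exchangeability.  The full
    grid is recomputed per permutation.  ``pairs`` (k x 2 array of
    (x column, y column)) restricts the recorded statistics to specific tests;
    ``orient`` supplies per-test orientation signs for ``signed_z``.
    """

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = doses.shape[0]
    null = []
    for _ in range(n_perm):
        perm = rng.permutation(n)
        scan = scan_ols(Y[perm], doses, C)
        s = scan_statistics(scan, statistic_kind, orient)
        if pairs is not None:
            s = s[pairs[:, 0], pairs[:, 1]]
        null.append(np.ravel(s))
    return PermutationNull(
        layer=layer, n_perm=n_perm, statistic_kind=statistic_kind,
        null_stats=np.vstack(null), seed=seed,
    )


def empirical_qvalues(observed, null: PermutationNull | np.ndarray) -> np.ndarray:
    """Empirical q-values from a permutation null (pooled-count estimator).

    FDRhat(t) = [mean over permutations of #{null >= t}] / max(1, #{obs >= t});
    q(s_i) = min over observed thresholds t <= s_i of FDRhat(t), capped at 1.
    Larger statistics are more significant.  NaN statistics get NaN q.
    """

    obs = np.asarray(observed, dtype=float).ravel()
    null_stats = null.null_stats if isinstance(null, PermutationNull) else np.asarray(null)
    n_perm = null_stats.shape[0]
    pooled = np.sort(null_stats.ravel())
    pooled = pooled[np.isfinite(pooled)]

    finite = np.isfinite(obs)
    vals = obs[finite]
    q = np.full(obs.shape, np.nan)
    if vals.size == 0:
        return q
    order = np.argsort(vals)  # ascending
    svals = vals[order]
    # counts of observed >= threshold, for thresholds = the observed values
    n_obs_ge = vals.size - np.searchsorted(svals, svals, side="left")
    n_null_ge = pooled.size - np.searchsorted(pooled, svals, side="left")
    fdr_hat = (n_null_ge / n_perm) / np.maximum(1, n_obs_ge)
    # running minimum over thresholds <= s (ascending order)
    q_sorted = np.minimum(np.minimum.accumulate(fdr_hat), 1.0)
    q_f = np.empty(vals.size)
    q_f[order] = q_sorted
    q[finite] = q_f
    return q


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaN-aware)."""

    p = np.asarray(pvals, dtype=float).ravel()
    q = np.full(p.shape, np.nan)
    finite = np.isfinite(p)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return q


def bh_threshold(pvals, alpha: float = 0.05) -> float:
    """Largest p among BH-rejected tests at level ``alpha`` (0.0 if none)."""

    p = np.asarray(pvals, dtype=float).ravel()
    p = p[np.isfinite(p)]
    if p.size == 0:
        return 0.0
    reject = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return float(p[reject].max()) if reject.any() else 0.0


def bh_layer_thresholds(p_cis, p_trans, alpha: float = 0.05) -> dict[str, float]:
    """Separate cis- and trans-specific BH significance thresholds."""

    return {
        "cis": bh_threshold(p_cis, alpha),
        "trans": bh_threshold(p_trans, alpha),
    }


def verify_bh_with_permutations(
    doses: np.ndarray,
    expr: np.ndarray,
    C,
    cis_mask: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Empirically confirm layer-wise BH thresholds by permutation.

    Runs the observed eQTL grid, derives the cis/trans BH thresholds, then
    permutes the expression sample labels ``n_perm`` times and estimates the
    realized FDR at those fixed thresholds as
    mean(null rejections) / max(1, observed rejections) per layer.
    """

    cis_mask = np.asarray(cis_mask, dtype=bool)
    scan = scan_ols(expr, doses, C)
    p = scan["p"]
    thresholds = bh_layer_thresholds(p[cis_mask], p[~cis_mask], alpha)
    n_obs = {
        "cis": int((p[cis_mask] <= thresholds["cis"]).sum()) if thresholds["cis"] > 0 else 0,
        "trans": int((p[~cis_mask] <= thresholds["trans"]).sum()) if thresholds["trans"] > 0 else 0,
    }
    rng = np.random.default_rng(seed)
    null_counts = {"cis": [], "trans": []}
    n = expr.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pp = scan_ols(expr[perm], doses, C)["p"]
        null_counts["cis"].append(
            int((pp[cis_mask] <= thresholds["cis"]).sum()) if thresholds["cis"] > 0 else 0
        )
        null_counts["trans"].append(
            int((pp[~cis_mask] <= thresholds["trans"]).sum()) if thresholds["trans"] > 0 else 0
        )
    report = {"alpha": alpha, "n_perm": n_perm, "seed": seed, "thresholds": thresholds}
    for layer in ("cis", "trans"):
        mean_null = float(np.mean(null_counts[layer])) if null_counts[layer] else 0.0
        report[layer] = {
            "n_observed_rejections": n_obs[layer],
            "mean_null_rejections": mean_null,
            "empirical_fdr": mean_null / max(1, n_obs[layer]),
        }
    return report
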