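"""Expression preprocessing chain.

Detection filtering, quantile normalization + log2, three sample-outlier
rules (expressed-gene count, Euclidean distance to a trimmed artificial
individual, Mahalanobis distance on QC features), batch adjustment and
residualization on covariates plus expression principal components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from trimetaqtl.assoc import residualize
from trimetaqtl.datatypes import CovariateTable, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SampleQcReport:
    """Per-sample outlier diagnostics; a flag set means the rule fired."""

    sample_ids: list[str]
    n_expressed: np.ndarray | None
    euclid_dist: np.ndarray
    mahalanobis_dist: np.ndarray | None
    flags: list[set] = field(default_factory=list)

    @property
    def outliers(self) -> list[str]:
        return [sid for sid, fl in zip(self.sample_ids, self.flags) if fl]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "n_expressed": self.n_expressed
                if self.n_expressed is not None
                else np.nan,
                "euclid_dist": self.euclid_dist,
                "mahalanobis_dist": self.mahalanobis_dist
                if self.mahalanobis_dist is not None
                else np.nan,
                "flags": [",".join(sorted(fl)) for fl in self.flags],
            }
        )


def filter_expressed(
    E: ExpressionMatrix,
    detection_p: np.ndarray,
    p_cut: float = 0.05,
    sample_frac: float = 0.05,
) -> ExpressionMatrix:
    """Keep probes detected (p <= ``p_cut``) in at least ``sample_frac`` of samples."""

    detection_p = np.asarray(detection_p, dtype=float)
    if detection_p.shape != E.values.shape:
        raise ValueError(
            f"detection_p shape {detection_p.shape} != expression shape {E.values.shape}"
        )
    frac = (detection_p <= p_cut).mean(axis=0)
    keep = frac >= sample_frac
    return E.subset_probes([p.probe_id for p, k in zip(E.probes, keep) if k])


def quantile_normalize_log2(E: ExpressionMatrix) -> ExpressionMatrix:
    """Map every sample's value distribution to the mean quantile profile, then log2.

    Ties within a sample receive the mean of the tied quantiles (average
    ranks interpolated into the reference profile).
    """

    X = E.values
    if np.any(X <= 0):
        raise ValueError("quantile normalization requires positive values")
    n, p = X.shape
    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    grid = np.arange(1, p + 1, dtype=float)
    for i in range(n):
        ranks = stats.rankdata(X[i], method="average")
        out[i] = np.interp(ranks, grid, reference)
    return E.with_values(np.log2(out))


def _median_iqr_cut(values: np.ndarray, k: float = 3.0) -> tuple[float, float]:
    med = float(np.median(values))
    q1, q3 = np.percentile(values, [25, 75])
    return med, float(q3 - q1) * k


def flag_sample_outliers(
    E: ExpressionMatrix,
    qc_features: pd.DataFrame | None = None,
    n_expressed: np.ndarray | None = None,
    iqr_mult: float = 3.0,
    trim_frac: float = 0.10,
) -> SampleQcReport:
    """Apply the three sample-outlier rules.

    1. expressed-gene count outside median +/- 3 IQR (needs ``n_expressed``);
    2. Euclidean distance to an artificial individual — the mean profile after
       removing the ceil(10% n) samples farthest from the plain mean — larger
       than median + 3 IQR;
    3. Mahalanobis distance of the QC-feature vector to the average QC
       individual larger than median + 3 IQR (needs ``qc_features``; a
       singular covariance is ridge-regularized with a warning).
    """

    X = E.values
    n = X.shape[0]
    if n < 10:
        raise ValueError(f"sample outlier rules need >= 10 samples, got {n}")
    flags: list[set] = [set() for _ in range(n)]

    if n_expressed is not None:
        n_expressed = np.asarray(n_expressed, dtype=float)
        med, cut = _median_iqr_cut(n_expressed, iqr_mult)
        for i in np.flatnonzero(np.abs(n_expressed - med) > cut):
            flags[i].add("count_outlier")

    plain_mean = X.mean(axis=0)
    d0 = np.linalg.norm(X - plain_mean, axis=1)
    n_trim = int(np.ceil(trim_frac * n))
    keep = np.argsort(d0)[: n - n_trim] if n_trim else np.arange(n)
    artificial = X[keep].mean(axis=0)
    euclid = np.linalg.norm(X - artificial, axis=1)
    med, cut = _median_iqr_cut(euclid, iqr_mult)
    for i in np.flatnonzero(euclid > med + cut):
        flags[i].add("euclid_outlier")

    maha = None
    qc = qc_features if qc_features is not None else E.qc_features
    if qc is not None:
        Q = np.asarray(qc, dtype=float)
        center = Q.mean(axis=0)
        cov = np.cov(Q, rowvar=False)
        cov = np.atleast_2d(cov)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            ridge = 1e-6 * np.trace(cov) / cov.shape[0]
            log.warning("singular QC covariance; regularizing with ridge %.3g", ridge)
            inv = np.linalg.inv(cov + ridge * np.eye(cov.shape[0]))
        diff = Q - center
        maha = np.sqrt(np.einsum("ij,jk,ik->i", diff, inv, diff))
        med, cut = _median_iqr_cut(maha, iqr_mult)
        for i in np.flatnonzero(maha > med + cut):
            flags[i].add("qc_outlier")

    return SampleQcReport(
        sample_ids=list(E.sample_ids),
        n_expressed=n_expressed,
        euclid_dist=euclid,
        mahalanobis_dist=maha,
        flags=flags,
    )


def adjust_batch(
    E: ExpressionMatrix,
    batch_labels,
    mode: str = "meanscale",
    prior_strength: float | None = None,
) -> ExpressionMatrix:
    """Remove known batch effects per probe.

    ``meanscale`` recenters each batch to the probe's grand mean and rescales
    each batch SD to the probe's overall SD.  ``eb`` shrinks the per-probe
    batch location and scale parameters toward their across-probe means with
    a moments-estimated normal / inverse-gamma prior before correcting
    (``prior_strength=inf`` forces identical corrections for all probes of a
    batch — the full-shrinkage limit).
    """

    if mode not in ("meanscale", "eb"):
        raise ValueError(f"unknown batch mode {mode!r}")
    labels = np.asarray(batch_labels)
    if labels.shape[0] != len(E.sample_ids):
        raise ValueError("batch label count != sample count")
    X = E.values
    batches = pd.unique(labels)
    for b in batches:
        if (labels == b).sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    grand_mean = X.mean(axis=0)
    grand_sd = X.std(axis=0, ddof=1)
    grand_sd = np.where(grand_sd == 0, 1.0, grand_sd)
    Z = (X - grand_mean) / grand_sd  # standardized per probe

    out = np.empty_like(Z)
    for b in batches:
        rows = labels == b
        nb = int(rows.sum())
        delta = Z[rows].mean(axis=0)  # per-probe batch offset (standardized)
        v = Z[rows].var(axis=0, ddof=1)
        v = np.where(v == 0, 1.0, v)
        if mode == "eb":
            gamma_b = delta.mean()
            vbar = v.mean()
            if prior_strength is not None and np.isinf(prior_strength):
                delta_star = np.full_like(delta, gamma_b)
                v_star = np.full_like(v, vbar)
            else:
                # location: normal prior, moment-estimated variance tau^2
                tau2 = max(delta.var() - 1.0 / nb, 1e-12)
                lam = tau2 / (tau2 + 1.0 / nb)
                delta_star = lam * delta + (1 - lam) * gamma_b
                # scale: inverse-gamma prior by moments on the batch variances
                s2 = max(v.var(), 1e-12)
                a = 2.0 + vbar**2 / s2
                bb = vbar * (a - 1.0)
                v_star = (bb + 0.5 * (nb - 1) * v) / (a - 1.0 + 0.5 * (nb - 1))
            out[rows] = (Z[rows] - delta_star) / np.sqrt(v_star)
        else:
            out[rows] = (Z[rows] - delta) / np.sqrt(v)
    corrected = out * grand_sd + grand_mean
    return E.with_values(corrected)


def residualize_expression(
    E: ExpressionMatrix,
    C: CovariateTable | None = None,
    n_pcs: int = 5,
    pcs: np.ndarray | None = None,
    return_pcs: bool = False,
):
    """Residualize each probe on covariates, then on the first ``n_pcs``
    principal components of the covariate-residualized matrix.

    Collinear covariate columns are dropped with a warning.  The output is
    orthogonal to every regressor (|r| < 1e-8).  ``pcs`` fixes the component
    scores to project out (instead of re-estimating them), which makes the
    step an idempotent projection; ``return_pcs`` also returns the scores
    used so they can be reapplied.
    """

    X = E.values
    Cmat = None
    if C is not None and C.columns:
        Cmat = C.matrix()
        # drop collinear columns (with intercept) by greedy rank check
        keep: list[int] = []
        base = np.ones((Cmat.shape[0], 1))
        for j in range(Cmat.shape[1]):
            cand = np.column_stack([base] + [Cmat[:, keep + [j]]]) \
                if keep else np.column_stack([base, Cmat[:, [j]]])
            if np.linalg.matrix_rank(cand) == cand.shape[1]:
                keep.append(j)
            else:
                log.warning(
                    "residualize_expression: dropping collinear covariate %r",
                    C.columns[j],
                )
        Cmat = Cmat[:, keep]
    R = residualize(X, Cmat)
    scores = pcs
    if scores is None and n_pcs > 0:
        # PCs of the covariate-residualized matrix; probe-centered by construction
        Rc = R - R.mean(axis=0)
        U, s, _ = np.linalg.svd(Rc, full_matrices=False)
        k = min(n_pcs, int((s > 1e-10 * s.max()).sum()) if s.size else 0)
        scores = U[:, :k] if k > 0 else None
    if scores is not None and scores.size:
        R = residualize(R, scores)
    out = E.with_values(R)
    return (out, scores) if return_pcs else out
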