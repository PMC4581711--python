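"""Causal inference for association triangles.

Two complementary tests for whether a transcript mediates a SNP–metabolite
association:

* adapted Mendelian randomization — the SNP instruments the transcript, but
  before forming the instrumental-variable ratio the metabolite is
  residualized for the SNP's remaining *direct* effect (the SNP coefficient
  of the joint metabolite ~ SNP + expression + covariates model).  Under a
  direct + mediated data-generating model this restores the IV ratio for the
  mediated path alone.
* beta-attenuation mediation test — the SNP coefficient of the metabolite
  model is compared with and without the transcript in the model; a positive
  drop in |beta| means expression explains part of the SNP–metabolite
  association.  It is the more conservative of the two and drives the
  causal conclusions.

Both use leave-one-out jackknife standard errors and a two-sided normal
reference.  The jackknife replicates are computed with the exact closed-form
leave-one-out OLS update (no refitting), which equals brute-force refitting
to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trimetaqtl.datatypes import CovariateTable, TriangleRecord


def _design(C, n: int) -> np.ndarray:
    if C is None:
        return np.empty((n, 0))
    if isinstance(C, CovariateTable):
        return C.matrix()
    C = np.asarray(C, dtype=float)
    return C[:, None] if C.ndim == 1 else C


def _ols_with_loo(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, np.ndarray]:
    """Coefficient j of OLS(y ~ X) and its exact leave-one-out replicates.

    beta_(-i) = beta - (X'X)^{-1} x_i e_i / (1 - h_i), evaluated at entry j.
    """

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    U = X @ XtX_inv                       # rows: (X'X)^{-1} x_i
    h = np.einsum("ij,ij->i", U, X)
    e = y - X @ beta
    loo = beta[j] - U[:, j] * e / (1.0 - h)
    return float(beta[j]), loo


def _jack_se(loo: np.ndarray) -> float:
    n = loo.size
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


@dataclass
class MrResult:
    """Adapted Mendelian randomization: metabolite change per unit expression."""

    beta_mr: float
    se_jack: float
    p: float | None
    direct_beta_removed: float
    n: int
    instrument_t: float
    weak_instrument: bool
    snp_id: str | None = None
    probe_id: str | None = None
    metabolite: str | None = None


@dataclass
class MediationResult:
    """Beta-attenuation mediation test: delta = |beta_without| - |beta_with|."""

    beta_without: float
    beta_with: float
    delta: float
    se_jack_delta: float
    p_delta: float
    n: int
    snp_id: str | None = None
    probe_id: str | None = None
    metabolite: str | None = None
    expl_var_mqtl: float | None = None
    expl_var_eqtl: float | None = None
    expl_var_exprmet: float | None = None


def _complete_cases(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        mask &= np.all(np.isfinite(a), axis=1) if a.ndim == 2 else np.isfinite(a)
    return mask


def mr_adapted(
    g, e, y, C: CovariateTable | np.ndarray | None = None,
    min_n: int = 30, weak_t: float = 2.0,
    ids: tuple[str, str, str] | None = None,
) -> MrResult:
    """Adapted MR of metabolite ``y`` on expression ``e`` instrumented by dose ``g``.

    Steps: (1) joint fit y ~ g + e + C gives the direct SNP coefficient c;
    (2) y* = y - c*g removes the direct path; (3) the covariate-adjusted IV
    ratio is beta(y* ~ g + C) / beta(e ~ g + C); (4) the jackknife SE repeats
    steps 1–3 leaving one sample out (closed form).  A weak instrument
    (|t| of e ~ g below ``weak_t``) is flagged and gets no p-value.
    """

    g = np.asarray(g, dtype=float).ravel()
    e = np.asarray(e, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    Cmat = _design(C, len(g))
    mask = _complete_cases(g, e, y, Cmat)
    n = int(mask.sum())
    if n < min_n:
        raise ValueError(f"too few complete cases for MR: n={n} < {min_n}")
    gm, em, ym, Cm = g[mask], e[mask], y[mask], Cmat[mask]
    ones = np.ones(n)

    X_ge = np.column_stack([ones, gm, Cm])           # e ~ g + C, y ~ g + C
    X_joint = np.column_stack([ones, gm, em, Cm])    # y ~ g + e + C

    b_eg, loo_eg = _ols_with_loo(X_ge, em, 1)
    # instrument relevance from the analytic t of e ~ g + C
    resid = em - X_ge @ np.linalg.lstsq(X_ge, em, rcond=None)[0]
    df = n - X_ge.shape[1]
    sigma2 = resid @ resid / df
    se_eg = np.sqrt(sigma2 * np.linalg.inv(X_ge.T @ X_ge)[1, 1])
    t_inst = b_eg / se_eg
    weak = abs(t_inst) < weak_t

    c, loo_c = _ols_with_loo(X_joint, ym, 1)
    b_yg, loo_yg = _ols_with_loo(X_ge, ym, 1)
    if b_eg == 0 or np.any(loo_eg == 0):
        raise ZeroDivisionError("zero instrument–exposure coefficient")
    beta_mr = (b_yg - c) / b_eg
    loo_mr = (loo_yg - loo_c) / loo_eg
    se = _jack_se(loo_mr)
    p = None if weak else float(2 * stats.norm.sf(abs(beta_mr) / se)) if se > 0 else None
    snp, probe, metab = ids if ids else (None, None, None)
    return MrResult(
        beta_mr=float(beta_mr), se_jack=se, p=p, direct_beta_removed=float(c),
        n=n, instrument_t=float(t_inst), weak_instrument=bool(weak),
        snp_id=snp, probe_id=probe, metabolite=metab,
    )


def mediation_attenuation_test(
    g, e, y, C: CovariateTable | np.ndarray | None = None,
    min_n: int = 30,
    ids: tuple[str, str, str] | None = None,
) -> MediationResult:
    """Test whether |beta_SNP| shrinks when expression enters the model.

    Both models use the same complete-case sample set (cases complete in g,
    e, y and covariates).  delta = |beta_without| - |beta_with| is tested
    against zero with a jackknife SE of the full two-model computation.
    """

    g = np.asarray(g, dtype=float).ravel()
    e = np.asarray(e, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    Cmat = _design(C, len(g))
    mask = _complete_cases(g, e, y, Cmat)
    n = int(mask.sum())
    if n < min_n:
        raise ValueError(f"too few complete cases for mediation test: n={n} < {min_n}")
    gm, em, ym, Cm = g[mask], e[mask], y[mask], Cmat[mask]
    ones = np.ones(n)
    X_without = np.column_stack([ones, gm, Cm])
    X_with = np.column_stack([ones, gm, em, Cm])
    b0, loo0 = _ols_with_loo(X_without, ym, 1)
    b1, loo1 = _ols_with_loo(X_with, ym, 1)
    delta = abs(b0) - abs(b1)
    loo_delta = np.abs(loo0) - np.abs(loo1)
    se = _jack_se(loo_delta)
    z = delta / se if se > 0 else np.inf * np.sign(delta)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    snp, probe, metab = ids if ids else (None, None, None)
    return MediationResult(
        beta_without=float(b0), beta_with=float(b1), delta=float(delta),
        se_jack_delta=se, p_delta=p, n=n,
        snp_id=snp, probe_id=probe, metabolite=metab,
    )


def summarize_causal(
    triangles: list[TriangleRecord],
    G,
    E_prepared,
    panel,
    C: CovariateTable | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-triangle causal report: the three edge estimates with explained
    variances, MR and mediation statistics; the best triple per SNP is
    flagged by minimal mediation p."""

    rows = []
    for t in triangles:
        g = G.dose(t.snp_id)
        e = E_prepared.expression(t.probe_id)
        y = panel.column(t.metabolite)
        ids = (t.snp_id, t.probe_id, t.metabolite)
        mr = mr_adapted(g, e, y, C, ids=ids)
        med = mediation_attenuation_test(g, e, y, C, ids=ids)
        rows.append(
            {
                "snp_id": t.snp_id, "probe_id": t.probe_id, "metabolite": t.metabolite,
                "cis_or_trans": t.cis_or_trans,
                "beta_mqtl": t.assoc_mqtl.beta, "beta_eqtl": t.assoc_eqtl.beta,
                "beta_exprmet": t.assoc_expr_metab.beta,
                "r2_mqtl": t.assoc_mqtl.explained_var,
                "r2_eqtl": t.assoc_eqtl.explained_var,
                "r2_exprmet": t.assoc_expr_metab.explained_var,
                "beta_mr": mr.beta_mr, "se_mr": mr.se_jack,
                "p_mr": np.nan if mr.p is None else mr.p,
                "weak_instrument": mr.weak_instrument,
                "beta_without": med.beta_without, "beta_with": med.beta_with,
                "delta": med.delta, "se_delta": med.se_jack_delta,
                "p_mediation": med.p_delta, "n": med.n,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        best = frame.groupby("snp_id")["p_mediation"].transform("min")
        frame["best_in_locus"] = frame["p_mediation"] == best
    return frame
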