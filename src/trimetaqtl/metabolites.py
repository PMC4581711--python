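"""Metabolite panel preprocessing.

The chain is: derive ratios/sums on the raw concentration scale, dichotomize
quantities with more than 20% of values below the limit of detection,
arsinh-transform the remaining quantities, then mask values outside
mean +/- 5 SD.  The panel's ``stage`` field enforces exactly this order.
"""

from __future__ import annotations

import logging

import numpy as np

from trimetaqtl.datatypes import MetaboliteDef, MetabolitePanel, PipelineOrderError

log = logging.getLogger(__name__)


def _require_stage(panel: MetabolitePanel, allowed: tuple[str, ...], op: str) -> None:
    if panel.stage not in allowed:
        raise PipelineOrderError(
            f"{op} requires panel stage in {allowed}, got {panel.stage!r}; "
            "legal order is derive -> dichotomize -> arsinh -> mask"
        )


def derive_quantities(
    panel: MetabolitePanel, defs: list[MetaboliteDef]
) -> MetabolitePanel:
    """Append ratio and sum quantities computed on the raw scale.

    A derived value is missing when any component is missing; a zero
    denominator sum also yields missing (counted and logged).  Below-LOD
    status propagates: a derived value is flagged when any component is
    below its LOD.
    """

    _require_stage(panel, ("raw",), "derive_quantities")
    n = len(panel.sample_ids)
    new_cols, new_lod, zero_denom = [], [], 0
    for d in defs:
        if d.kind not in ("ratio", "sum"):
            raise ValueError(f"{d.name}: derive_quantities handles ratio/sum, got {d.kind}")
        for comp in tuple(d.numerator) + tuple(d.denominator):
            if comp not in panel.names:
                raise KeyError(f"{d.name}: unknown raw metabolite {comp!r}")
        num = np.sum([panel.column(c) for c in d.numerator], axis=0)
        flag = np.any([panel.below_lod[:, panel.column_index(c)] for c in d.numerator], axis=0)
        if d.kind == "sum":
            vals = num
        else:
            den = np.sum([panel.column(c) for c in d.denominator], axis=0)
            flag |= np.any(
                [panel.below_lod[:, panel.column_index(c)] for c in d.denominator], axis=0
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                vals = num / den
            zero = np.isfinite(num) & (den == 0)
            zero_denom += int(zero.sum())
            vals = np.where(zero, np.nan, vals)
        new_cols.append(vals)
        new_lod.append(flag & np.isfinite(vals))
    if zero_denom:
        log.warning("derive_quantities: %d zero-denominator values set missing", zero_denom)
    values = np.column_stack([panel.values] + [c[:, None] for c in new_cols]) \
        if new_cols else panel.values.copy()
    lod = np.column_stack([panel.below_lod] + [f[:, None] for f in new_lod]) \
        if new_cols else panel.below_lod.copy()
    return MetabolitePanel(
        panel.sample_ids, list(panel.defs) + list(defs), values, lod, stage="derived"
    )


def dichotomize_by_lod(
    panel: MetabolitePanel, frac_threshold: float = 0.20
) -> MetabolitePanel:
    """Dichotomize quantities with strictly more than ``frac_threshold`` of
    non-missing values below the limit of detection (0 = below, 1 = above)."""

    _require_stage(panel, ("raw", "derived"), "dichotomize_by_lod")
    values = panel.values.copy()
    defs = list(panel.defs)
    for j, d in enumerate(defs):
        col = panel.values[:, j]
        obs = np.isfinite(col)
        if not obs.any():
            continue
        frac_below = panel.below_lod[obs, j].mean()
        if frac_below > frac_threshold:
            new = np.where(obs, (~panel.below_lod[:, j]).astype(float), np.nan)
            values[:, j] = new
            defs[j] = MetaboliteDef(
                name=d.name, kind="dichotomized",
                numerator=d.numerator, denominator=d.denominator, lod=d.lod,
            )
    return MetabolitePanel(
        panel.sample_ids, defs, values, panel.below_lod, stage="dichotomized"
    )


def arsinh_transform(panel: MetabolitePanel) -> MetabolitePanel:
    """Apply x -> ln(x + sqrt(x^2 + 1)) to non-dichotomized columns.

    The inverse hyperbolic sine behaves like a log for large concentrations
    but is defined at zero; raw concentrations must be nonnegative.
    """

    _require_stage(panel, ("raw", "derived", "dichotomized"), "arsinh_transform")
    values = panel.values.copy()
    for j, d in enumerate(panel.defs):
        if d.kind == "dichotomized":
            continue
        col = values[:, j]
        if np.any(col[np.isfinite(col)] < 0):
            raise ValueError(f"negative raw concentration in {d.name!r}")
        values[:, j] = np.arcsinh(col)
    return MetabolitePanel(
        panel.sample_ids, list(panel.defs), values, panel.below_lod, stage="transformed"
    )


def mask_outliers(panel: MetabolitePanel, k: float = 5.0) -> MetabolitePanel:
    """Set values outside mean +/- k*SD of their column to missing.

    Column statistics are computed once on the non-missing values (single
    pass, no re-estimation).  Dichotomized columns and zero-SD columns are
    left untouched (the latter with a warning).
    """

    _require_stage(panel, ("transformed",), "mask_outliers")
    values = panel.values.copy()
    for j, d in enumerate(panel.defs):
        if d.kind == "dichotomized":
            continue
        col = values[:, j]
        obs = np.isfinite(col)
        if obs.sum() < 2:
            continue
        mu = col[obs].mean()
        sd = col[obs].std(ddof=1)
        if sd == 0:
            log.warning("mask_outliers: column %r has zero SD, nothing masked", d.name)
            continue
        if not np.isfinite(k):
            continue
        out = obs & (np.abs(col - mu) > k * sd)
        values[out, j] = np.nan
    return MetabolitePanel(
        panel.sample_ids, list(panel.defs), values, panel.below_lod, stage="masked"
    )


def prepare_panel(
    panel: MetabolitePanel,
    derived_defs: list[MetaboliteDef] | None = None,
    lod_frac: float = 0.20,
    outlier_sd: float = 5.0,
) -> MetabolitePanel:
    """Full preprocessing chain in the enforced order."""

    out = derive_quantities(panel, derived_defs or [])
    out = dichotomize_by_lod(out, lod_frac)
    out = arsinh_transform(out)
    return mask_outliers(out, outlier_sd)
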