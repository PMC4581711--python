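"""Shared domain containers for genotype, expression, metabolite and result data.

All matrices are oriented samples x features.  Sample identity is carried by an
ordered list of string ids; every container exposes ``subset_samples`` so that
cohort harmonization (intersection of ids) is a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


class PipelineOrderError(RuntimeError):
    """Raised when metabolite preprocessing steps are applied out of order."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpRecord:
    """One biallelic variant with imputation metadata.

    ``maf`` is the minor allele frequency (0..0.5); ``info`` the imputation
    information score (0..1), used to filter replication proxies.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_ref: str = "A"
    allele_alt: str = "G"
    maf: float = np.nan
    info: float = 1.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if np.isfinite(self.maf) and not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if not (0.0 <= self.info <= 1.0):
            raise ValidationError(f"{self.snp_id}: info {self.info} outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Gene-dose matrix (samples x SNPs), doses continuous in [0, 2]."""

    sample_ids: list[str]
    snps: list[SnpRecord]
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != (len(self.sample_ids), len(self.snps)):
            raise ValidationError(
                f"dose matrix shape {self.doses.shape} != "
                f"({len(self.sample_ids)}, {len(self.snps)})"
            )
        bad = np.argwhere((self.doses < 0) | (self.doses > 2))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"dose {self.doses[i, j]} outside [0, 2] at sample "
                f"{self.sample_ids[i]!r}, snp {self.snps[j].snp_id!r}"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise ValidationError(f"duplicate snp_id {dup!r}")
        self._index = {sid: j for j, sid in enumerate(ids)}

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp_id {snp_id!r}") from None

    def snp(self, snp_id: str) -> SnpRecord:
        return self.snps[self.snp_index(snp_id)]

    def dose(self, snp_id: str) -> np.ndarray:
        return self.doses[:, self.snp_index(snp_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = _sample_indexer(self.sample_ids, sample_ids)
        return GenotypeMatrix(list(sample_ids), self.snps, self.doses[idx])

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.snp_index(s) for s in snp_ids]
        return GenotypeMatrix(
            self.sample_ids, [self.snps[c] for c in cols], self.doses[:, cols]
        )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeRecord:
    """Expression probe with its genomic placement; center may be half-integral."""

    probe_id: str
    gene_symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.probe_id}: start {self.start} > end {self.end}")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class ExpressionMatrix:
    """Expression values (samples x probes) with optional per-sample QC features."""

    sample_ids: list[str]
    probes: list[ProbeRecord]
    values: np.ndarray
    qc_features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probes)):
            raise ValidationError(
                f"expression shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.probes)})"
            )
        self._index = {p.probe_id: j for j, p in enumerate(self.probes)}

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._index[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe_id {probe_id!r}") from None

    def probe(self, probe_id: str) -> ProbeRecord:
        return self.probes[self.probe_index(probe_id)]

    def expression(self, probe_id: str) -> np.ndarray:
        return self.values[:, self.probe_index(probe_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = _sample_indexer(self.sample_ids, sample_ids)
        qc = None
        if self.qc_features is not None:
            qc = self.qc_features.iloc[idx].reset_index(drop=True)
        return ExpressionMatrix(list(sample_ids), self.probes, self.values[idx], qc)

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        cols = [self.probe_index(p) for p in probe_ids]
        return ExpressionMatrix(
            self.sample_ids,
            [self.probes[c] for c in cols],
            self.values[:, cols],
            self.qc_features,
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.sample_ids, self.probes, values, self.qc_features)


# ---------------------------------------------------------------------------
# metabolites
# ---------------------------------------------------------------------------

VALID_METABOLITE_KINDS = ("raw", "ratio", "sum", "dichotomized")


@dataclass(frozen=True)
class MetaboliteDef:
    """Definition of an analyzed quantity.

    ``ratio`` quantities are (sum of numerator)/(sum of denominator) of raw
    analytes on the concentration scale; ``sum`` quantities add raw analytes.
    ``lod`` is the limit of detection of a raw analyte (absent for derived
    quantities).
    """

    name: str
    kind: str = "raw"
    numerator: tuple[str, ...] = ()
    denominator: tuple[str, ...] = ()
    lod: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_METABOLITE_KINDS:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "ratio" and (not self.numerator or not self.denominator):
            raise ValidationError(f"{self.name}: ratio needs numerator and denominator")
        if self.kind == "sum" and (len(self.numerator) < 2 or self.denominator):
            raise ValidationError(
                f"{self.name}: sum needs >=2 numerator terms and no denominator"
            )
        if self.lod is not None and self.lod < 0:
            raise ValidationError(f"{self.name}: negative lod")


# Preprocessing stage ordering (derive -> dichotomize -> transform -> mask).
STAGES = ("raw", "derived", "dichotomized", "transformed", "masked")


@dataclass
class MetabolitePanel:
    """Metabolite quantities (samples x quantities) with missing and LOD masks.

    ``values`` uses NaN for missing; ``below_lod`` flags measured-below-LOD
    cells.  ``stage`` tracks how far the preprocessing chain has run so the
    derive -> dichotomize -> arsinh -> outlier-mask order can be enforced.
    """

    sample_ids: list[str]
    defs: list[MetaboliteDef]
    values: np.ndarray
    below_lod: np.ndarray | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.defs)):
            raise ValidationError(
                f"metabolite shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.defs)})"
            )
        if self.below_lod is None:
            self.below_lod = np.zeros(self.values.shape, dtype=bool)
        self.below_lod = np.asarray(self.below_lod, dtype=bool)
        if self.below_lod.shape != self.values.shape:
            raise ValidationError("below_lod mask shape mismatch")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        for j, d in enumerate(self.defs):
            if d.kind == "dichotomized":
                col = self.values[:, j]
                ok = np.isnan(col) | (col == 0) | (col == 1)
                if not ok.all():
                    raise ValidationError(
                        f"dichotomized column {d.name!r} contains non-binary values"
                    )
        self._index = {d.name: j for j, d in enumerate(self.defs)}

    @property
    def transformed(self) -> bool:
        return self.stage in ("transformed", "masked")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.defs]

    def column_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown metabolite {name!r}") from None

    def definition(self, name: str) -> MetaboliteDef:
        return self.defs[self.column_index(name)]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_index(name)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MetabolitePanel":
        idx = _sample_indexer(self.sample_ids, sample_ids)
        return MetabolitePanel(
            list(sample_ids), self.defs, self.values[idx], self.below_lod[idx], self.stage
        )

    def replace(self, **kw) -> "MetabolitePanel":
        base = dict(
            sample_ids=self.sample_ids,
            defs=self.defs,
            values=self.values,
            below_lod=self.below_lod,
            stage=self.stage,
        )
        base.update(kw)
        return MetabolitePanel(**base)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """Named covariates (samples x columns), each tagged continuous or binary."""

    sample_ids: list[str]
    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.data) != len(self.sample_ids):
            raise ValidationError("covariate row count != sample count")
        self.data = self.data.reset_index(drop=True).astype(float)
        for col in self.data.columns:
            kind = self.kinds.get(col)
            if kind is None:
                vals = self.data[col].dropna().unique()
                kind = "binary" if set(vals) <= {0.0, 1.0} else "continuous"
                self.kinds[col] = kind
            if kind == "binary":
                vals = set(self.data[col].dropna().unique())
                if not vals <= {0.0, 1.0}:
                    raise ValidationError(f"binary covariate {col!r} not in {{0,1}}")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CovariateTable":
        idx = _sample_indexer(self.sample_ids, sample_ids)
        return CovariateTable(
            list(sample_ids), self.data.iloc[idx].reset_index(drop=True), dict(self.kinds)
        )

    def select(self, columns: Sequence[str]) -> "CovariateTable":
        return CovariateTable(
            self.sample_ids,
            self.data[list(columns)].copy(),
            {c: self.kinds[c] for c in columns},
        )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

ASSOCIATION_LAYERS = ("mqtl", "eqtl_cis", "eqtl_trans", "expr_metab")

#: column order of an association table (one AssociationRecord per row)
ASSOCIATION_COLUMNS = [
    "x_id", "y_id", "layer", "beta", "se", "t", "p", "q", "n", "explained_var",
]


@dataclass(frozen=True)
class AssociationRecord:
    """One covariate-adjusted linear association between two quantities."""

    x_id: str
    y_id: str
    layer: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    explained_var: float
    q: float | None = None

    def __post_init__(self) -> None:
        if self.layer not in ASSOCIATION_LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"p {self.p} outside (0, 1]")
        if self.se <= 0:
            raise ValidationError(f"se {self.se} not positive")
        if np.sign(self.t) != np.sign(self.beta) and self.beta != 0:
            raise ValidationError("sign(t) != sign(beta)")
        if not (0.0 <= self.explained_var <= 1.0):
            raise ValidationError("explained_var outside [0, 1]")


def associations_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    rows = [
        {
            "x_id": r.x_id, "y_id": r.y_id, "layer": r.layer, "beta": r.beta,
            "se": r.se, "t": r.t, "p": r.p,
            "q": np.nan if r.q is None else r.q,
            "n": r.n, "explained_var": r.explained_var,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)


def frame_to_associations(frame: pd.DataFrame) -> list[AssociationRecord]:
    out = []
    for row in frame.itertuples(index=False):
        q = getattr(row, "q", np.nan)
        out.append(
            AssociationRecord(
                x_id=row.x_id, y_id=row.y_id, layer=row.layer, beta=row.beta,
                se=row.se, t=row.t, p=row.p, n=int(row.n),
                explained_var=row.explained_var,
                q=None if q is None or (isinstance(q, float) and np.isnan(q)) else q,
            )
        )
    return out


@dataclass(frozen=True)
class TriangleRecord:
    """A SNP–probe–metabolite triple whose three pairwise edges are significant."""

    snp_id: str
    probe_id: str
    metabolite: str
    assoc_mqtl: AssociationRecord
    assoc_eqtl: AssociationRecord
    assoc_expr_metab: AssociationRecord
    cis_or_trans: str

    def __post_init__(self) -> None:
        if self.assoc_mqtl.x_id != self.snp_id or self.assoc_mqtl.y_id != self.metabolite:
            raise ValidationError("mQTL edge ids do not match triangle ids")
        if self.assoc_eqtl.x_id != self.snp_id or self.assoc_eqtl.y_id != self.probe_id:
            raise ValidationError("eQTL edge ids do not match triangle ids")
        if (self.assoc_expr_metab.x_id != self.probe_id
                or self.assoc_expr_metab.y_id != self.metabolite):
            raise ValidationError("expression–metabolite edge ids do not match")
        if self.cis_or_trans not in ("cis", "trans"):
            raise ValidationError(f"cis_or_trans {self.cis_or_trans!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sample_indexer(have: Sequence[str], want: Sequence[str]) -> np.ndarray:
    pos = {sid: i for i, sid in enumerate(have)}
    missing = [s for s in want if s not in pos]
    if missing:
        raise KeyError(f"sample ids not present: {missing[:5]}")
    return np.asarray([pos[s] for s in want], dtype=int)


def harmonize_samples(*objects):
    """Restrict containers to their common samples, preserving first object's order.

    Returns the harmonized containers plus the ordered intersection.  Raises
    ``ValidationError`` when the intersection is empty.
    """

    common = None
    for obj in objects:
        ids = set(obj.sample_ids)
        common = ids if common is None else (common & ids)
    if not common:
        raise ValidationError("no samples shared between inputs")
    ordered = [s for s in objects[0].sample_ids if s in common]
    return tuple(obj.subset_samples(ordered) for obj in objects) + (ordered,)
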