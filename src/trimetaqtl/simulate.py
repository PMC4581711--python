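"""Synthetic two-cohort multi-omics generator with planted ground truth.

The generator emulates the data structure the pipeline expects from a
genotyped, expression-profiled and metabolite-phenotyped cohort:

* gene doses in [0, 2] with block LD built from founder-haplotype pools
  (no recombination within a block, independence across blocks) and a small
  truncated dosage noise mimicking imputation;
* expression with planted cis (<= 1 Mb) and trans regulatory effects plus
  per-batch shifts, emitted both on a latent Gaussian scale and as positive
  intensities for the normalization chain;
* metabolites built from direct SNP effects, expression-mediated effects and
  covariate effects on a latent scale, exponentiated to a skewed positive
  concentration scale with a per-column limit of detection;
* a replication cohort drawing independent individuals from the same founder
  pools with identical true effect sizes, optionally dropping a fraction of
  SNPs to exercise proxy search.

Every planted effect is recorded in a :class:`TruthTable` so downstream
stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trimetaqtl.datatypes import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeMatrix,
    MetaboliteDef,
    MetabolitePanel,
    ProbeRecord,
    SnpRecord,
    ValidationError,
)

EFFECT_KINDS = (
    "snp_metab_direct",
    "snp_probe_cis",
    "snp_probe_trans",
    "probe_metab",
    "snp_probe_metab_mediated",
)


@dataclass(frozen=True)
class PlantedEffect:
    kind: str
    snp_id: str | None = None
    probe_id: str | None = None
    metabolite: str | None = None
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValidationError(f"unknown effect kind {self.kind!r}")


@dataclass
class TruthTable:
    """Planted effects; mediated entries are markers tying a snp->probe effect
    to a probe->metabolite effect for the same triple."""

    effects: list[PlantedEffect]

    def of_kind(self, kind: str) -> list[PlantedEffect]:
        return [e for e in self.effects if e.kind == kind]

    def mqtl_pairs(self) -> list[tuple[str, str]]:
        """All (snp, metabolite) pairs with a marginal association: direct
        effects plus mediated chains."""

        pairs = [(e.snp_id, e.metabolite) for e in self.of_kind("snp_metab_direct")]
        pairs += [(e.snp_id, e.metabolite) for e in self.of_kind("snp_probe_metab_mediated")]
        return pairs

    def eqtl_pairs(self) -> list[tuple[str, str]]:
        return [
            (e.snp_id, e.probe_id)
            for e in self.effects
            if e.kind in ("snp_probe_cis", "snp_probe_trans")
        ]

    def mediated_triples(self) -> list[tuple[str, str, str]]:
        return [
            (e.snp_id, e.probe_id, e.metabolite)
            for e in self.of_kind("snp_probe_metab_mediated")
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": e.kind,
                    "snp_id": e.snp_id or "",
                    "probe_id": e.probe_id or "",
                    "metabolite": e.metabolite or "",
                    "beta": e.beta,
                }
                for e in self.effects
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TruthTable":
        effects = [
            PlantedEffect(
                kind=r.kind,
                snp_id=r.snp_id or None,
                probe_id=r.probe_id or None,
                metabolite=r.metabolite or None,
                beta=float(r.beta),
            )
            for r in frame.itertuples(index=False)
        ]
        return cls(effects)


@dataclass
class SimConfig:
    """Study conditions of the synthetic design.

    Defaults describe a discovery cohort of 2000 and a replication cohort of
    1000 individuals, 500 SNPs in 5-SNP LD blocks drawn from pools of 10
    founder haplotypes, 120 expression probes, 24 metabolite quantities and
    20 planted effects (8 direct SNP->metabolite, 4 mediated
    SNP->probe->metabolite chains contributing a cis eQTL and an
    expression->metabolite effect each, 2 standalone cis eQTLs and 2 trans
    eQTLs).
    """

    n_discovery: int = 2000
    n_replication: int = 1000
    n_snps: int = 500
    n_probes: int = 120
    n_metabolites: int = 24
    ld_block_size: int = 5
    haplotype_pool: int = 10
    maf_range: tuple[float, float] = (0.10, 0.45)
    dose_noise_sd: float = 0.05
    n_chromosomes: int = 4
    block_spacing_bp: int = 2_000_000
    snp_spacing_bp: int = 5_000
    batch_count: int = 4
    batch_shift_sd: float = 0.3
    lod_quantile: float = 0.02
    n_high_lod: int = 2        # trailing metabolite columns with high LOD
    high_lod_quantile: float = 0.30
    n_unexpressed_probes: int = 6
    metab_noise_sd: float = 1.0
    latent_shift: float = 3.0  # raw concentration = exp(latent + shift)
    intensity_log2_offset: float = 8.0
    replication_drop_frac: float = 0.10
    effects: list[PlantedEffect] | None = None
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("n_discovery", "n_replication", "n_snps", "n_probes",
                     "n_metabolites", "ld_block_size", "haplotype_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        return self


# ---------------------------------------------------------------------------
# default planted design
# ---------------------------------------------------------------------------

def _snp_name(i: int) -> str:
    return f"snp{i + 1:04d}"


def _probe_name(i: int) -> str:
    return f"probe{i + 1:03d}"


def _metab_name(i: int) -> str:
    return f"M{i + 1:02d}"


def default_effects(cfg: SimConfig) -> list[PlantedEffect]:
    """The default 20-effect design on separate LD blocks.

    Effect sizes (SD units per dose / per unit latent expression) are chosen
    so that every planted mQTL clears the 1e-7 discovery cut-off with high
    probability at n = 2000 and mediated chains yield detectable triangles:
    direct SNP->metabolite 0.30, mediated chains 0.70 (cis) x 0.50
    (expression->metabolite, marginal SNP effect 0.35), standalone cis eQTLs
    0.50 and trans eQTLs 0.40.
    """

    bs = cfg.ld_block_size
    n_blocks = cfg.n_snps // bs

    def lead(block: int) -> str:
        return _snp_name((block % n_blocks) * bs)

    effects: list[PlantedEffect] = []
    # 8 direct mQTLs
    for i in range(8):
        effects.append(
            PlantedEffect("snp_metab_direct", snp_id=lead(i),
                          metabolite=_metab_name(i), beta=0.30)
        )
    # 4 mediated chains (cis eQTL + expression->metabolite)
    for i in range(4):
        snp, probe, metab = lead(8 + i), _probe_name(i), _metab_name(8 + i)
        effects.append(PlantedEffect("snp_probe_cis", snp_id=snp, probe_id=probe, beta=0.70))
        effects.append(PlantedEffect("probe_metab", probe_id=probe, metabolite=metab, beta=0.50))
        effects.append(
            PlantedEffect("snp_probe_metab_mediated", snp_id=snp, probe_id=probe,
                          metabolite=metab, beta=0.35)
        )
    # 2 standalone cis eQTLs, 2 trans eQTLs
    for i in range(2):
        effects.append(
            PlantedEffect("snp_probe_cis", snp_id=lead(12 + i),
                          probe_id=_probe_name(4 + i), beta=0.50)
        )
    for i in range(2):
        effects.append(
            PlantedEffect("snp_probe_trans", snp_id=lead(14 + i),
                          probe_id=_probe_name(6 + i), beta=0.40)
        )
    return effects


def default_derived_defs() -> list[MetaboliteDef]:
    """A ratio and a sum over null raw metabolites, mirroring derived GWAS traits."""

    return [
        MetaboliteDef("M13_M14_ratio", kind="ratio", numerator=("M13",), denominator=("M14",)),
        MetaboliteDef("M15_M16_sum", kind="sum", numerator=("M15", "M16")),
    ]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class _FounderPanel:
    """Shared founder haplotypes + SNP metadata; both cohorts sample from it."""

    snps: list[SnpRecord]
    block_of: np.ndarray          # block index per SNP
    founders: list[np.ndarray]    # per block: (haplotype_pool, block_size) 0/1


def _build_founder_panel(cfg: SimConfig, rng: np.random.Generator) -> _FounderPanel:
    bs, H = cfg.ld_block_size, cfg.haplotype_pool
    n_blocks = int(np.ceil(cfg.n_snps / bs))
    snps: list[SnpRecord] = []
    block_of = np.empty(cfg.n_snps, dtype=int)
    founders: list[np.ndarray] = []
    blocks_per_chrom = int(np.ceil(n_blocks / cfg.n_chromosomes))
    for b in range(n_blocks):
        chrom = str(b // blocks_per_chrom + 1)
        chrom_block = b % blocks_per_chrom
        base = 1 + chrom_block * cfg.block_spacing_bp
        f_block = rng.uniform(*cfg.maf_range)
        perm = rng.permutation(H)
        nested = True if b < 16 else rng.random() < 0.5  # planted blocks stay taggable
        hap = np.zeros((H, bs), dtype=np.int8)
        size = min(bs, cfg.n_snps - b * bs)
        for s in range(size):
            i = b * bs + s
            f = float(np.clip(f_block + rng.uniform(-0.02, 0.02), 0.02, 0.5))
            c = int(np.clip(round(f * H), 1, H - 1))
            carriers = perm[:c] if nested else rng.choice(H, size=c, replace=False)
            hap[carriers, s] = 1
            maf = min(c / H, 1 - c / H)
            snps.append(
                SnpRecord(
                    snp_id=_snp_name(i), chrom=chrom,
                    pos=base + s * cfg.snp_spacing_bp, maf=maf, info=1.0,
                )
            )
            block_of[i] = b
        founders.append(hap[:, :size])
    return _FounderPanel(snps=snps, block_of=block_of, founders=founders)


def _sample_genotypes(
    panel: _FounderPanel, n: int, cfg: SimConfig, rng: np.random.Generator
) -> GenotypeMatrix:
    if n < 2:
        raise ValueError("need n >= 2 individuals")
    H = cfg.haplotype_pool
    cols = []
    for hap in panel.founders:
        a = hap[rng.integers(0, H, size=n)]
        b = hap[rng.integers(0, H, size=n)]
        cols.append((a + b).astype(float))
    doses = np.concatenate(cols, axis=1)
    if cfg.dose_noise_sd > 0:
        doses = np.clip(doses + rng.normal(0, cfg.dose_noise_sd, doses.shape), 0.0, 2.0)
    # imputation info: 1 - noise variance over dose variance
    var = doses.var(axis=0, ddof=1)
    info = np.clip(1.0 - cfg.dose_noise_sd**2 / np.maximum(var, 1e-12), 0.0, 1.0)
    snps = [
        SnpRecord(s.snp_id, s.chrom, s.pos, s.allele_ref, s.allele_alt, s.maf,
                  float(info[j]))
        for j, s in enumerate(panel.snps)
    ]
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, snps, doses)


def simulate_genotypes(n: int, cfg: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Stand-alone genotype simulation (own founder pool)."""

    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    panel = _build_founder_panel(cfg, rng)
    return _sample_genotypes(panel, n, cfg, rng)


# ---------------------------------------------------------------------------
# probes / expression
# ---------------------------------------------------------------------------

def _build_probes(
    G_snps: list[SnpRecord], truth: TruthTable, cfg: SimConfig, rng: np.random.Generator
) -> list[ProbeRecord]:
    by_id = {s.snp_id: s for s in G_snps}
    chroms = sorted({s.chrom for s in G_snps}, key=int)
    max_pos = max(s.pos for s in G_snps)
    placed: dict[str, ProbeRecord] = {}
    for e in truth.effects:
        if e.kind not in ("snp_probe_cis", "snp_probe_trans") or e.probe_id in placed:
            continue
        snp = by_id[e.snp_id]
        if e.kind == "snp_probe_cis":
            center = snp.pos + int(rng.integers(-200_000, 200_000))
            start = max(1, center - 500)
            probe = ProbeRecord(e.probe_id, e.probe_id.upper(), snp.chrom, start, start + 1000)
            if abs(snp.pos - probe.center) > 1_000_000:
                raise ValidationError(
                    f"cis probe {e.probe_id} placed > 1 Mb from {e.snp_id}"
                )
        else:
            other = [c for c in chroms if c != snp.chrom]
            chrom = other[int(rng.integers(len(other)))] if other else snp.chrom
            start = int(rng.integers(1, max_pos))
            probe = ProbeRecord(e.probe_id, e.probe_id.upper(), chrom, start, start + 1000)
        placed[e.probe_id] = probe
    probes = []
    for i in range(cfg.n_probes):
        pid = _probe_name(i)
        if pid in placed:
            probes.append(placed[pid])
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(1, max_pos))
            probes.append(ProbeRecord(pid, pid.upper(), chrom, start, start + 1000))
    return probes


def simulate_expression(
    G: GenotypeMatrix,
    truth: TruthTable,
    cfg: SimConfig,
    seed: int | None = None,
    probes: list[ProbeRecord] | None = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Latent-scale expression: planted dose effects + batch shifts + N(0,1) noise.

    Returns the expression matrix and the per-sample batch labels.  Probe
    coordinates place cis targets within 1 Mb of their SNP and trans targets
    on another chromosome.
    """

    rng = np.random.default_rng(cfg.seed + 11 if seed is None else seed)
    if probes is None:
        probes = _build_probes(G.snps, truth, cfg, rng)
    probe_idx = {p.probe_id: j for j, p in enumerate(probes)}
    snp_by_id = {s.snp_id: s for s in G.snps}
    n = len(G.sample_ids)
    values = rng.normal(0.0, 1.0, size=(n, len(probes)))
    batch = np.arange(n) % cfg.batch_count
    if cfg.batch_shift_sd > 0:
        shifts = rng.normal(0, cfg.batch_shift_sd, size=(cfg.batch_count, len(probes)))
        values += shifts[batch]
    for e in truth.effects:
        if e.kind not in ("snp_probe_cis", "snp_probe_trans"):
            continue
        if e.snp_id not in snp_by_id:
            raise ValidationError(f"planted effect references unknown SNP {e.snp_id!r}")
        j = probe_idx[e.probe_id]
        probe = probes[j]
        dist_ok = (probe.chrom == snp_by_id[e.snp_id].chrom
                   and abs(snp_by_id[e.snp_id].pos - probe.center) <= 1_000_000)
        if e.kind == "snp_probe_cis" and not dist_ok:
            raise ValidationError(f"cis effect {e.snp_id}->{e.probe_id} placed > 1 Mb away")
        values[:, j] += e.beta * G.dose(e.snp_id)
    qc = pd.DataFrame(
        rng.normal(0, 1, size=(n, 3)), columns=["qc_pm_ratio", "qc_neg_ctrl", "qc_housekeeping"]
    )
    return ExpressionMatrix(list(G.sample_ids), probes, values, qc), batch


def detection_pvalues(
    E: ExpressionMatrix, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Detection p-value matrix: the trailing ``n_unexpressed_probes`` probes are
    below the noise floor in ~98% of samples and get filtered out."""

    n, p = E.values.shape
    det = rng.uniform(0.0, 0.04, size=(n, p))
    n_un = min(cfg.n_unexpressed_probes, p)
    if n_un:
        det[:, p - n_un:] = rng.uniform(0.06, 1.0, size=(n, n_un))
        flip = rng.random((n, n_un)) < 0.02
        det[:, p - n_un:][flip] = 0.01
    return det


# ---------------------------------------------------------------------------
# covariates / metabolites
# ---------------------------------------------------------------------------

def simulate_covariates(n: int, rng: np.random.Generator) -> CovariateTable:
    """Age ~ N(60, 10^2), sex ~ Bernoulli(0.5), three genetic PCs ~ N(0, 1)."""

    data = pd.DataFrame(
        {
            "age": rng.normal(60, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "pc1": rng.normal(0, 1, n),
            "pc2": rng.normal(0, 1, n),
            "pc3": rng.normal(0, 1, n),
        }
    )
    return CovariateTable([f"S{i + 1:05d}" for i in range(n)],
                          data, {"age": "continuous", "sex": "binary",
                                 "pc1": "continuous", "pc2": "continuous",
                                 "pc3": "continuous"})


def simulate_metabolites(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    C: CovariateTable,
    truth: TruthTable,
    cfg: SimConfig,
    seed: int | None = None,
) -> MetabolitePanel:
    """Raw-scale metabolites with planted direct, mediated and covariate effects.

    latent = sum(direct beta * dose) + sum(probe beta * expression)
             + covariate effects + N(0, noise^2); raw = exp(latent + shift).
    Values below each column's ``lod_quantile`` (``high_lod_quantile`` for the
    trailing ``n_high_lod`` columns) are flagged below-LOD.
    """

    rng = np.random.default_rng(cfg.seed + 23 if seed is None else seed)
    n = len(G.sample_ids)
    q = cfg.n_metabolites
    latent = rng.normal(0.0, cfg.metab_noise_sd, size=(n, q))
    age = C.data["age"].to_numpy() if "age" in C.columns else np.zeros(n)
    sex = C.data["sex"].to_numpy() if "sex" in C.columns else np.zeros(n)
    for j in range(q):
        if j % 2 == 1:  # covariate effects on odd columns
            latent[:, j] += 0.01 * (age - 60.0) + 0.25 * sex
    names = [_metab_name(j) for j in range(q)]
    col = {nm: j for j, nm in enumerate(names)}
    for e in truth.effects:
        if e.kind == "snp_metab_direct":
            latent[:, col[e.metabolite]] += e.beta * G.dose(e.snp_id)
        elif e.kind == "probe_metab":
            latent[:, col[e.metabolite]] += e.beta * E.expression(e.probe_id)
    raw = np.exp(latent + cfg.latent_shift)
    lod_q = np.full(q, cfg.lod_quantile)
    if cfg.n_high_lod:
        lod_q[q - cfg.n_high_lod:] = cfg.high_lod_quantile
    below = np.zeros_like(raw, dtype=bool)
    defs = []
    for j in range(q):
        lod = float(np.quantile(raw[:, j], lod_q[j]))
        below[:, j] = raw[:, j] < lod
        defs.append(MetaboliteDef(names[j], kind="raw", lod=lod))
    return MetabolitePanel(list(G.sample_ids), defs, raw, below, stage="raw")


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """Everything generated for one cohort."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix          # positive intensities (2^(latent+offset))
    expression_latent: ExpressionMatrix   # latent Gaussian scale
    detection_p: np.ndarray
    batch_labels: np.ndarray
    metabolites: MetabolitePanel          # raw concentration scale
    covariates: CovariateTable


@dataclass
class StudyData:
    discovery: CohortBundle
    replication: CohortBundle
    truth: TruthTable
    config: SimConfig = field(repr=False, default=None)


def _make_cohort(
    panel: _FounderPanel,
    probes: list[ProbeRecord],
    n: int,
    truth: TruthTable,
    cfg: SimConfig,
    rng: np.random.Generator,
    prefix: str,
) -> CohortBundle:
    G = _sample_genotypes(panel, n, cfg, rng)
    sample_ids = [f"{prefix}{i + 1:05d}" for i in range(n)]
    G = GenotypeMatrix(sample_ids, G.snps, G.doses)
    E_lat, batch = simulate_expression(
        G, truth, cfg, seed=int(rng.integers(2**31)), probes=probes
    )
    C = simulate_covariates(n, rng)
    C = CovariateTable(sample_ids, C.data, dict(C.kinds))
    M = simulate_metabolites(G, E_lat, C, truth, cfg, seed=int(rng.integers(2**31)))
    det = detection_pvalues(E_lat, cfg, rng)
    intensities = np.power(2.0, E_lat.values + cfg.intensity_log2_offset)
    E_int = ExpressionMatrix(sample_ids, E_lat.probes, intensities, E_lat.qc_features)
    return CohortBundle(
        genotypes=G, expression=E_int, expression_latent=E_lat,
        detection_p=det, batch_labels=batch, metabolites=M, covariates=C,
    )


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> StudyData:
    """Generate discovery and replication cohorts sharing SNP panel and truth.

    The two cohorts draw independent individuals from the same founder
    haplotype pools; the replication panel drops a random
    ``replication_drop_frac`` of SNPs so lead SNPs sometimes need proxies.
    """

    cfg = (cfg or SimConfig()).validate()
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(master)
    panel = _build_founder_panel(cfg, rng)
    effects = cfg.effects if cfg.effects is not None else default_effects(cfg)
    truth = TruthTable(list(effects))
    probes = _build_probes(panel.snps, truth, cfg, rng)

    disc = _make_cohort(panel, probes, cfg.n_discovery, truth, cfg,
                        np.random.default_rng(master + 1), "D")
    rep = _make_cohort(panel, probes, cfg.n_replication, truth, cfg,
                       np.random.default_rng(master + 2), "R")
    if cfg.replication_drop_frac > 0:
        drop_rng = np.random.default_rng(master + 3)
        n_snps = len(rep.genotypes.snps)
        n_drop = int(round(cfg.replication_drop_frac * n_snps))
        dropped = set(drop_rng.choice(n_snps, size=n_drop, replace=False).tolist())
        keep_ids = [s.snp_id for j, s in enumerate(rep.genotypes.snps) if j not in dropped]
        rep.genotypes = rep.genotypes.subset_snps(keep_ids)
    return StudyData(discovery=disc, replication=rep, truth=truth, config=cfg)
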