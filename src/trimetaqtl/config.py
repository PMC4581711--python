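"""Run configuration: analysis thresholds with study defaults, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Pipeline thresholds and constants.

    Defaults follow the two-stage mQTL study design: a liberal discovery
    cut-off of 1e-7, study-wide FDR control at 5% via 1000 phenotype-link
    permutations, LD pruning at r^2 < 0.3, replication proxies within
    +/-50 kb at r^2 > 0.8 and imputation info > 0.3, a 1 Mb (inclusive)
    cis window, 100 permutations for eQTL-FDR confirmation and for the
    association-triangle null, mean +/- 5 SD outlier masking and
    dichotomization of metabolites with more than 20% of values below the
    limit of detection.
    """

    discovery_p: float = 1.0e-7
    fdr: float = 0.05
    prune_r2: float = 0.3
    proxy_r2: float = 0.8
    proxy_window_bp: int = 50_000
    proxy_info_min: float = 0.3
    cis_window_bp: int = 1_000_000
    locus_merge_bp: int = 1_000_000
    n_perm_mqtl: int = 1000
    n_perm_eqtl: int = 100
    n_perm_triangle: int = 100
    outlier_sd: float = 5.0
    lod_dichotomize_frac: float = 0.20
    n_expression_pcs: int = 5
    # triangle null: rerun lead-SNP pruning inside each permutation (True) or
    # freeze the observed leads (False)
    reprune_in_triangle_null: bool = True
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        checks = [
            ("discovery_p", 0 < self.discovery_p <= 1),
            ("fdr", 0 < self.fdr < 1),
            ("prune_r2", 0 < self.prune_r2 <= 1),
            ("proxy_r2", 0 < self.proxy_r2 <= 1),
            ("proxy_window_bp", self.proxy_window_bp > 0),
            ("proxy_info_min", 0 <= self.proxy_info_min <= 1),
            ("cis_window_bp", self.cis_window_bp > 0),
            ("locus_merge_bp", self.locus_merge_bp > 0),
            ("n_perm_mqtl", self.n_perm_mqtl >= 1),
            ("n_perm_eqtl", self.n_perm_eqtl >= 1),
            ("n_perm_triangle", self.n_perm_triangle >= 1),
            ("outlier_sd", self.outlier_sd > 0),
            ("lod_dichotomize_frac", 0 <= self.lod_dichotomize_frac < 1),
            ("n_expression_pcs", self.n_expression_pcs >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"config value out of range: {name}={getattr(self, name)}")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config, filling defaults and rejecting unknown keys."""

    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - valid)
    if unknown:
        raise ValueError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    return RunConfig(**data).validate()
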