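import numpy as np
import pytest

from trimetaqtl.datatypes import (
    CovariateTable,
    MetaboliteDef,
    MetabolitePanel,
)
from trimetaqtl.simulate import PlantedEffect, SimConfig, simulate_study

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_covariates(rng):
    n = 200
    data = pd.DataFrame(
        {"age": rng.normal(60, 10, n), "sex": rng.integers(0, 2, n).astype(float)}
    )
    return CovariateTable([f"S{i:04d}" for i in range(n)], data)


def make_panel(values, names=None, below_lod=None, stage="raw", kinds=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, q = values.shape
    names = names or [f"m{j}" for j in range(q)]
    kinds = kinds or ["raw"] * q
    defs = [MetaboliteDef(nm, kind=k) for nm, k in zip(names, kinds)]
    return MetabolitePanel(
        [f"S{i:04d}" for i in range(n)], defs, values, below_lod, stage=stage
    )


@pytest.fixture(scope="session")
def small_study():
    """A compact two-cohort study with the default planted design, shared by
    pipeline-level tests (session-scoped: simulation is deterministic)."""

    cfg = SimConfig(
        n_discovery=600, n_replication=400, n_snps=120, n_probes=40,
        n_metabolites=16, seed=77,
        effects=[
            PlantedEffect("snp_metab_direct", snp_id="snp0001", metabolite="M01", beta=0.6),
            PlantedEffect("snp_metab_direct", snp_id="snp0006", metabolite="M02", beta=0.6),
            PlantedEffect("snp_probe_cis", snp_id="snp0011", probe_id="probe001", beta=0.9),
            PlantedEffect("probe_metab", probe_id="probe001", metabolite="M03", beta=0.7),
            PlantedEffect("snp_probe_metab_mediated", snp_id="snp0011",
                          probe_id="probe001", metabolite="M03", beta=0.63),
            PlantedEffect("snp_probe_trans", snp_id="snp0016", probe_id="probe002", beta=0.8),
        ],
    )
    return simulate_study(cfg)
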