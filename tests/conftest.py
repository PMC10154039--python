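"""Shared fixtures: small seeded synthetic datasets."""

import warnings

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

import leukotraj as lt

warnings.filterwarnings("ignore", category=UserWarning)


def small_programs():
    return [
        lt.ProgramSpec("tps", 20, 2.0,
                       {"differentiation": "down", "transformation": "up"}),
        lt.ProgramSpec("differentiation", 25, 1.5, {"differentiation": "up"}),
        lt.ProgramSpec("stemness", 20, 1.5, {"differentiation": "down"}),
        lt.ProgramSpec("leukemia", 25, 1.5, {"transformation": "up"}),
        lt.ProgramSpec("anti_tps", 15, 1.5, {"transformation": "down"}),
        lt.ProgramSpec("splicing_factors", 20, 1.2,
                       {"differentiation": "up", "transformation": "up"},
                       ramp="time"),
    ]


@pytest.fixture(scope="session")
def small_config():
    return lt.SimulationConfig(
        n_genes=600,
        n_cells_per_stage={"T0": 120, "T1": 140, "T2": 140, "T3": 140},
        program_specs=small_programs(),
        n_s_genes=15, n_g2m_genes=15,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return lt.simulate_bifurcation(small_config)


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    adata, truth = small_dataset
    filtered, _ = lt.filter_cells_genes(adata)
    return lt.normalize_log2(filtered), truth


def toy_counts(n_genes=8, n_cells=6, seed=0, mito_genes=()):
    """Tiny AnnData with explicit integer counts for arithmetic checks."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 20, size=(n_cells, n_genes))
    genes = [f"g{j}" for j in range(n_genes)]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    var = pd.DataFrame({"chromosome": "chr1",
                        "start": np.arange(n_genes) * 1000,
                        "mito": [g in mito_genes for g in genes]},
                       index=genes)
    return AnnData(X=X, obs=obs, var=var)
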