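import numpy as np
import pandas as pd
import pytest

from cistrans.config import FilterConfig, SimConfig
from cistrans.formats_io import (GenotypeMatrix, HOM_REF, HET, HOM_ALT,
                                 MISSING)


@pytest.fixture
def filters():
    return FilterConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(genotype_rows, populations, positions=None, scaffold="scaf1"):
    """Build a GenotypeMatrix from a list of per-site genotype lists."""
    gt = np.asarray(genotype_rows, dtype=np.int8)
    n_sites, n_samples = gt.shape
    samples = [f"s{i+1}" for i in range(n_samples)]
    if positions is None:
        positions = list(range(100, 100 + 1000 * n_sites, 1000))
    sites = pd.DataFrame({
        "scaffold": [scaffold] * n_sites,
        "position": positions,
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
    })
    pops = dict(zip(samples, populations))
    return GenotypeMatrix(sites, gt, np.full(gt.shape, 99.0), samples, pops)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete synthetic experiment, shared across tests."""
    from cistrans.synthetic_data import simulate_dataset

    cfg = SimConfig(n_genes=120, n_fixed_snps=25, n_differentiated_snps=40,
                    n_background_snps=60, n_fixed_deletions=12,
                    n_background_svs=80, n_crosses=2, stages=("2dpf",),
                    n_per_group={"2dpf": (6, 6, 3)}, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_pipeline_result(tmp_path_factory):
    """Full pipeline run on a small synthetic dataset with planted truth."""
    from cistrans import pipeline as pl

    cfg = {
        "seed": 3,
        "synthetic": {
            "n_genes": 100, "n_fixed_snps": 20, "n_differentiated_snps": 30,
            "n_background_snps": 50, "n_fixed_deletions": 10,
            "n_background_svs": 50, "n_crosses": 1, "stages": ["2dpf"],
            "n_per_group": {"2dpf": [6, 6, 3]}, "seed": 3,
        },
        "filters": {"n_ase_sims": 2000},
    }
    out = tmp_path_factory.mktemp("pipeline")
    return pl.run_full_analysis(cfg=cfg, outdir=out), cfg, out
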