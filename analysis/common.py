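"""Shared configuration for the numbered analysis scripts.

The scripts run in order: 01 generates the study-shaped synthetic dataset
and executes the full pipeline once, writing every stage table under
results/tables/; the later scripts read those tables and distil the
stage-specific summaries under results/.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
TABLES = RESULTS / "tables"

SEED = 1

# Study-shaped conditions: 157 fixed SNPs and 87 fixed deletions among
# 80,012 structural variants; 600 genes with 90% conserved regimes,
# |effect| = 1.5 log2, 100x SNV coverage, 6 vs 6 purebreds and 3 F1 hybrids
# in one cross at one stage; ASE null simulated 10,000 times per gene.
PIPELINE_CONFIG = {
    "seed": SEED,
    "synthetic": {
        "n_genes": 600,
        "n_fixed_snps": 157,
        "n_fixed_deletions": 87,
        "n_background_svs": 80_012 - 87,
        "n_crosses": 1,
        "stages": ["2dpf"],
        "n_per_group": {"2dpf": [6, 6, 3]},
        "seed": SEED,
    },
    "filters": {"n_ase_sims": 10_000},
}


def load_table(name: str) -> pd.DataFrame:
    path = TABLES / f"{name}.tsv"
    if not path.exists():
        raise SystemExit(
            f"{path} not found - run analysis/01_simulate_and_run.py first")
    return pd.read_csv(path, sep="\t")


def save(df: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", index=False)
    return path
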