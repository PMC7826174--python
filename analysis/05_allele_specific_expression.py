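"""Summarize the gene-level allele-specific-expression tests.

Each testable (hybrid sample, gene) pair gets an aggregate major-allele
frequency and an empirical p-value from the simulated pseudo-phased null.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_table, save


def main() -> None:
    ase = load_table("ase_results")
    per_sample = (ase.groupby("sample_id")
                  .agg(n_genes_tested=("gene_id", "size"),
                       n_significant=("significant", "sum"),
                       median_maf=("maf", lambda s: round(s.median(), 3)))
                  .reset_index())
    per_gene = ase.groupby("gene_id")["significant"].agg(["sum", "size"])
    all_hybrids = int((per_gene["sum"] == per_gene["size"]).sum())
    summary = pd.DataFrame([{
        "n_tests": len(ase),
        "n_significant_tests": int(ase["significant"].sum()),
        "n_genes_ase_in_all_hybrids": all_hybrids,
    }])
    save(per_sample, "05_ase_per_sample.tsv")
    path = save(summary, "05_ase_summary.tsv")
    print(f"{all_hybrids} genes show significant ASE in every hybrid of "
          "their cross.")
    print(per_sample.to_string(index=False))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
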