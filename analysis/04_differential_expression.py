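"""Summarize the four differential-expression contrasts per cross/stage.

The parents contrast feeds the regulatory classification; the three
hybrid-versus-parent contrasts feed the inheritance-mode calls.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_table, save


def main() -> None:
    de = load_table("de_results")
    summary = (de.groupby(["cross_id", "stage", "contrast"])
               .agg(n_genes=("gene_id", "size"),
                    n_significant=("significant", "sum"),
                    median_abs_lfc=("lfc", lambda s: round(s.abs().median(), 3)))
               .reset_index())
    path = save(summary, "04_de_summary.tsv")
    parents = summary[summary["contrast"] == "parents"]
    print("Differential expression at FDR 0.01 "
          f"(parents contrast: {int(parents['n_significant'].iloc[0])} of "
          f"{int(parents['n_genes'].iloc[0])} genes).")
    print(summary.to_string(index=False))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
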