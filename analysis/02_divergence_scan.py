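"""Summarize the divergence scan: how much of the genome separates the two
populations, and how rare fixed variation is.

Expected picture (mirrors the study design): a handful of fixed SNPs
(Fst = 1) and fixed deletions against a large background of shared and
merely differentiated variation.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_table, save


def main() -> None:
    sites = load_table("site_divergence")
    fixed_snps = load_table("fixed_snps")
    fixed_svs = load_table("fixed_svs")
    wins = load_table("windows_near")

    finite = sites["fst"].dropna()
    summary = pd.DataFrame([{
        "n_snps_scanned": len(sites),
        "mean_fst": round(float(finite.mean()), 4),
        "fst_99th_pct": round(float(finite.quantile(0.99)), 4),
        "n_fixed_snps": len(fixed_snps),
        "n_fixed_deletions": len(fixed_svs),
        "fixed_deletion_bp_min": int(fixed_svs["length"].min()),
        "fixed_deletion_bp_max": int(fixed_svs["length"].max()),
        "n_windows_10kb": len(wins),
        "dxy_90th_pct": round(float(wins["dxy"].quantile(0.90)), 4),
    }])
    path = save(summary, "02_divergence_summary.tsv")
    print("Divergence scan: fixed variation is rare relative to the "
          "scanned background.")
    print(summary.to_string(index=False))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
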