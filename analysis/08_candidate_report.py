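"""Distil the final candidate list and check it against the planted truth.

A top candidate needs a linked fixed variant within 10 kb, significant
parental differential expression, and a cis classification — the pattern
that singled out the two candidate genes in the source system.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_table, save


def main() -> None:
    report = load_table("candidate_report")
    truth = load_table("truth").set_index("gene_id")
    report["planted_regime"] = [
        truth.loc[g, "regime"] for g in report["gene_id"]]
    report["planted_variant"] = [
        truth.loc[g, "linked_variant"] for g in report["gene_id"]]
    path = save(report, "08_candidate_report.tsv")
    planted = truth[(truth["regime"] == "cis")
                    & truth["linked_variant"].str.startswith(
                        "fixed_", na=False)]
    hit = set(report["gene_id"]) == set(planted.index)
    print(f"{len(report)} candidate genes "
          f"({'exactly' if hit else 'NOT exactly'} the planted cis genes "
          "next to fixed variants):")
    print(report.to_string(index=False))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
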