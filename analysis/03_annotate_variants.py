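"""Associate fixed variants with nearby genes and label genomic context.

Links every fixed SNP and deletion to genes whose span lies within 10 kb,
and tabulates where fixed variants fall (exonic / intronic / proximal /
intergenic).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_table, save


def main() -> None:
    links = load_table("variant_gene_links")
    ctx = load_table("variant_context")

    by_context = (ctx.groupby(["variant_type", "context"]).size()
                  .rename("n").reset_index())
    linked_genes = links["gene_id"].nunique()
    summary = pd.DataFrame([{
        "n_fixed_variants": len(ctx),
        "n_variant_gene_links_10kb": len(links),
        "n_genes_near_fixed_variants": linked_genes,
        "min_abs_distance_bp": int(links["distance"].abs().min()),
    }])
    save(by_context, "03_variant_context_counts.tsv")
    path = save(summary, "03_annotation_summary.tsv")
    print(f"{len(ctx)} fixed variants; {linked_genes} genes within 10 kb "
          "of at least one.")
    print(by_context.to_string(index=False))
    print(f"written to {path}")


if __name__ == "__main__":
    main()
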