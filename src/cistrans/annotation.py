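"""Associate variants with nearby genes and classify genomic context.

A variant links to a gene when its span intersects the gene span padded by
the window on both sides (inclusive bounds, "within 10 kb" means <= 10,000
bp).  Distances are signed genomic distances: 0 when the variant overlaps
the gene span, negative upstream of the first exon, positive downstream of
the last exon — strand is recorded on the gene, not folded into the sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .formats_io import GeneModel


@dataclass
class VariantGeneLink:
    variant_id: str
    variant_type: str  # "SNP" or an SV type
    scaffold: str
    start: int
    end: int
    gene_id: str
    distance: int  # signed bp; 0 if overlapping the gene span
    window_bp: int


def _signed_distance(v_start: int, v_end: int, span: tuple) -> int:
    s, e = span
    if v_end < s:
        return v_end - s  # negative: upstream of first exon
    if v_start > e:
        return v_start - e  # positive: downstream of last exon
    return 0


def associate_variants_with_genes(variants, genes: Sequence[GeneModel],
                                  window_bp: int = 10_000) -> list:
    """All (variant, gene) links within ``window_bp`` of the gene span.

    ``variants`` is an iterable of (variant_id, variant_type, scaffold,
    start, end) tuples (for SNPs start == end); a pandas DataFrame with those
    columns is also accepted.  One link per pair; a variant may link several
    genes.
    """
    if isinstance(variants, pd.DataFrame):
        variants = list(variants[["variant_id", "variant_type", "scaffold",
                                  "start", "end"]].itertuples(index=False))
    by_scaffold = {}
    for gm in genes:
        by_scaffold.setdefault(gm.scaffold, []).append(gm)
    for lst in by_scaffold.values():
        lst.sort(key=lambda g: g.span)
    links = []
    for vid, vtype, scaf, v_start, v_end in variants:
        v_start, v_end = int(v_start), int(v_end)
        for gm in by_scaffold.get(scaf, ()):
            s, e = gm.span
            if v_end >= s - window_bp and v_start <= e + window_bp:
                links.append(VariantGeneLink(
                    str(vid), str(vtype), scaf, v_start, v_end, gm.gene_id,
                    _signed_distance(v_start, v_end, gm.span), window_bp))
    return links


def links_to_frame(links: Sequence[VariantGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.variant_id, l.variant_type, l.scaffold, l.start, l.end,
          l.gene_id, l.distance, l.window_bp) for l in links],
        columns=["variant_id", "variant_type", "scaffold", "start", "end",
                 "gene_id", "distance", "window_bp"])


def variant_context(scaffold: str, start: int, end: int,
                    genes: Sequence[GeneModel],
                    window_near: int = 10_000) -> tuple:
    """Context label and fully-contained exons for one variant span.

    Returns ``(label, contained_exons)`` with label in {"exonic",
    "intronic", "proximal_noncoding", "intergenic"}; ``contained_exons`` is a
    list of (gene_id, exon_index) for exons entirely inside the variant span
    (1-based exon indices in genomic order).
    """
    exonic = intronic = proximal = False
    contained = []
    for gm in genes:
        if gm.scaffold != scaffold:
            continue
        s, e = gm.span
        overlaps_span = end >= s and start <= e
        hits_exon = False
        for k, (xs, xe) in enumerate(gm.exons, 1):
            if end >= xs and start <= xe:
                hits_exon = True
                if start <= xs and end >= xe:
                    contained.append((gm.gene_id, k))
        if hits_exon:
            exonic = True
        elif overlaps_span:
            intronic = True
        elif end >= s - window_near and start <= e + window_near:
            proximal = True
    if exonic:
        return "exonic", contained
    if intronic:
        return "intronic", []
    if proximal:
        return "proximal_noncoding", []
    return "intergenic", []
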