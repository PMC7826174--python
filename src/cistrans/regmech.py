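"""Classify the regulatory mechanism and inheritance mode of each gene.

For every gene in a cross at a stage, three quantities are combined:

* the hybrid allelic ratio H = (sum maternal + 0.5) / (sum paternal + 0.5)
  over informative SNVs and hybrid replicates;
* the parental expression ratio P = (mean normalized purebred count of the
  maternal population + 0.5) / (same, paternal population + 0.5);
* a two-sided Fisher's exact test T on the 2x2 table
  [[hybrid maternal, hybrid paternal], [parental maternal, parental
  paternal]] for a trans contribution (the null: the parental ratio equals
  the hybrid allelic ratio).

Categories: a differentially expressed gene with allele-specific expression
in all hybrids and no significant T is *cis*; differentially expressed with
no ASE and significant T is *trans*; ASE with significant T and no
differential expression is compensatory (*cis x trans*, opposing signs of
log2 H and log2 P) or reinforcing (*cis + trans*, same sign); no DE and no
ASE is conserved; every other combination is ambiguous.  |log2 ratio| within
the sign deadzone counts as sign zero and can satisfy neither sign clause.

Inheritance in hybrids is read from the four pairwise DE contrasts
(A vs B, A vs hybrid, B vs hybrid, parents-pooled vs hybrid) in precedence
order transgressive (over-/underdominant: hybrid differs from both parents
in the same direction) > dominant (differs from exactly one parent) >
additive (parents differ and the hybrid mean lies strictly between them) >
undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("cis", "trans", "cis_x_trans", "cis_plus_trans",
              "conserved", "ambiguous")
INHERITANCE_MODES = ("additive", "dominant", "overdominant",
                     "underdominant", "undetermined")


@dataclass
class RegulatoryCall:
    gene_id: str
    cross_id: str
    stage: str
    hybrid_ratio: float  # H
    parental_ratio: float  # P
    log2_hybrid_ratio: float
    log2_parental_ratio: float
    trans_p: float
    de_significant: bool
    ase_all_hybrids: bool
    ase_any_hybrid: bool
    category: str


@dataclass
class InheritanceCall:
    gene_id: str
    cross_id: str
    stage: str
    mode: str
    dominant_toward: str  # parental population label, or ""


def regulatory_ratios(hybrid_maternal_total: float,
                      hybrid_paternal_total: float,
                      maternal_pop_mean: float,
                      paternal_pop_mean: float,
                      pseudocount: float = 0.5) -> tuple:
    """(H, P, log2 H, log2 P) with the pseudocount guard on every term."""
    for v in (hybrid_maternal_total, hybrid_paternal_total,
              maternal_pop_mean, paternal_pop_mean):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    h = (hybrid_maternal_total + pseudocount) / (hybrid_paternal_total + pseudocount)
    p = (maternal_pop_mean + pseudocount) / (paternal_pop_mean + pseudocount)
    return h, p, float(np.log2(h)), float(np.log2(p))


def trans_contribution_test(hybrid_maternal: int, hybrid_paternal: int,
                            parent_maternal: int, parent_paternal: int) -> float:
    """Two-sided Fisher's exact p for a trans contribution.

    A zero margin makes the table degenerate; p = 1 by convention.
    """
    table = np.array([[hybrid_maternal, hybrid_paternal],
                      [parent_maternal, parent_paternal]], dtype=np.int64)
    if np.any(table < 0):
        raise ValueError("table entries must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.debug("degenerate 2x2 table %s: p = 1", table.tolist())
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _sign(x: float, deadzone: float) -> int:
    if abs(x) <= deadzone:
        return 0
    return 1 if x > 0 else -1


def classify_regulatory_mechanism(de_significant: bool,
                                  ase_flags,
                                  trans_p: float,
                                  log2_hybrid_ratio: float,
                                  log2_parental_ratio: float,
                                  alpha_t: float = 0.05,
                                  sign_deadzone: float = 0.05,
                                  ase_none_rule: str = "not_all") -> str:
    """Assign exactly one regulatory category to a testable gene.

    ``ase_flags`` is the per-hybrid significance of the ASE test for this
    gene in this cross/stage.  "Shows ASE" means significant in every
    hybrid; "no ASE" defaults to the complement of that (``ase_none_rule=
    "not_all"``), with ``"no_hybrid"`` (no hybrid individually significant)
    available.
    """
    flags = [bool(f) for f in ase_flags]
    if not flags:
        raise ValueError("at least one hybrid ASE flag required")
    ase_all = all(flags)
    if ase_none_rule == "not_all":
        ase_none = not ase_all
    elif ase_none_rule == "no_hybrid":
        ase_none = not any(flags)
    else:
        raise ValueError(f"unknown ase_none_rule {ase_none_rule!r}")
    t_sig = trans_p < alpha_t
    s_h = _sign(log2_hybrid_ratio, sign_deadzone)
    s_p = _sign(log2_parental_ratio, sign_deadzone)

    if ase_all and de_significant and not t_sig:
        return "cis"
    if ase_none and de_significant and t_sig:
        return "trans"
    if ase_all and t_sig and not de_significant:
        if s_h != 0 and s_p != 0 and s_h != s_p:
            return "cis_x_trans"
        if s_h != 0 and s_p != 0 and s_h == s_p:
            return "cis_plus_trans"
        return "ambiguous"
    if ase_none and not de_significant:
        return "conserved"
    return "ambiguous"


def classify_inheritance(parents_differ: bool,
                         hybrid_vs_maternal: bool,
                         hybrid_vs_paternal: bool,
                         hybrid_mean: float,
                         maternal_mean: float,
                         paternal_mean: float,
                         gene_id: str = "", cross_id: str = "",
                         stage: str = "",
                         maternal_population: str = "maternal",
                         paternal_population: str = "paternal") -> InheritanceCall:
    """Inheritance mode from the pairwise DE contrasts and group means.

    Boolean arguments are the significance flags of the corresponding
    contrasts; means are normalized expression means.
    """
    above_both = (hybrid_vs_maternal and hybrid_vs_paternal
                  and hybrid_mean > maternal_mean
                  and hybrid_mean > paternal_mean)
    below_both = (hybrid_vs_maternal and hybrid_vs_paternal
                  and hybrid_mean < maternal_mean
                  and hybrid_mean < paternal_mean)
    if above_both:
        mode, toward = "overdominant", ""
    elif below_both:
        mode, toward = "underdominant", ""
    elif hybrid_vs_maternal != hybrid_vs_paternal:
        mode = "dominant"
        # indistinguishable from one parent: expression resembles that parent
        toward = (paternal_population if hybrid_vs_maternal
                  else maternal_population)
    elif parents_differ and (min(maternal_mean, paternal_mean) < hybrid_mean
                             < max(maternal_mean, paternal_mean)):
        mode, toward = "additive", ""
    else:
        mode, toward = "undetermined", ""
    return InheritanceCall(gene_id, cross_id, stage, mode, toward)


# ---------------------------------------------------------------------------
# table-level drivers


def regulatory_calls(gene_ids,
                     allele_counts: pd.DataFrame,
                     ase_results: pd.DataFrame,
                     de_results: pd.DataFrame,
                     norm_counts: pd.DataFrame,
                     maternal_samples, paternal_samples, hybrid_samples,
                     cross_id: str, stage: str,
                     filters=None) -> pd.DataFrame:
    """Regulatory-mechanism calls for all testable genes of one cross/stage.

    ``allele_counts`` holds the per-SNV hybrid counts (restricted to this
    cross/stage), ``ase_results`` the per-(sample, gene) ASE table,
    ``de_results`` the parental DE table, and ``norm_counts`` the normalized
    count matrix.  Genes failing the informative-SNV/coverage requirement
    are marked untestable and omitted.
    """
    from .config import FilterConfig

    filters = filters or FilterConfig()
    de_sig = dict(zip(de_results["gene_id"], de_results["significant"]))
    ase_by_gene = {}
    for row in ase_results.itertuples():
        ase_by_gene.setdefault(row.gene_id, {})[row.sample_id] = row.significant

    rows = []
    by_gene = dict(tuple(allele_counts.groupby("gene_id", sort=False)))
    for gene_id in gene_ids:
        sub = by_gene.get(gene_id)
        if sub is None or sub.empty or gene_id not in norm_counts.index:
            continue
        totals = (sub["maternal_count"] + sub["paternal_count"]).to_numpy()
        usable = sub[totals >= filters.min_snv_coverage]
        n_snvs = usable.groupby(["scaffold", "position"]).ngroups
        if n_snvs < filters.min_informative_snvs:
            continue  # untestable for mechanism
        hyb_mat = int(usable["maternal_count"].sum())
        hyb_pat = int(usable["paternal_count"].sum())
        mat_mean = float(norm_counts.loc[gene_id, list(maternal_samples)].mean())
        pat_mean = float(norm_counts.loc[gene_id, list(paternal_samples)].mean())
        h, p, l2h, l2p = regulatory_ratios(
            hyb_mat, hyb_pat, mat_mean, pat_mean, filters.ratio_pseudocount)
        if filters.fisher_parent_counts == "mean":
            par_mat = int(np.rint(mat_mean))
            par_pat = int(np.rint(pat_mean))
        else:
            par_mat = int(np.rint(
                norm_counts.loc[gene_id, list(maternal_samples)].sum()))
            par_pat = int(np.rint(
                norm_counts.loc[gene_id, list(paternal_samples)].sum()))
        t_p = trans_contribution_test(hyb_mat, hyb_pat, par_mat, par_pat)
        flags_by_sample = ase_by_gene.get(gene_id, {})
        flags = [bool(flags_by_sample.get(s, False)) for s in hybrid_samples]
        if not flags:
            continue
        category = classify_regulatory_mechanism(
            bool(de_sig.get(gene_id, False)), flags, t_p, l2h, l2p,
            alpha_t=filters.alpha_t, sign_deadzone=filters.sign_deadzone,
            ase_none_rule=filters.ase_none_rule)
        rows.append((gene_id, cross_id, stage, h, p, l2h, l2p, t_p,
                     bool(de_sig.get(gene_id, False)), all(flags),
                     any(flags), category))
    return pd.DataFrame(rows, columns=[
        "gene_id", "cross_id", "stage", "hybrid_ratio", "parental_ratio",
        "log2_hybrid_ratio", "log2_parental_ratio", "trans_p",
        "de_significant", "ase_all_hybrids", "ase_any_hybrid", "category"])


def inheritance_calls(de_parents: pd.DataFrame,
                      de_hybrid_vs_maternal: pd.DataFrame,
                      de_hybrid_vs_paternal: pd.DataFrame,
                      norm_counts: pd.DataFrame,
                      maternal_samples, paternal_samples, hybrid_samples,
                      cross_id: str, stage: str,
                      maternal_population: str = "maternal",
                      paternal_population: str = "paternal") -> pd.DataFrame:
    """Inheritance-mode calls for every gene with all contrasts available."""
    pd_sig = dict(zip(de_parents["gene_id"], de_parents["significant"]))
    hm_sig = dict(zip(de_hybrid_vs_maternal["gene_id"],
                      de_hybrid_vs_maternal["significant"]))
    hp_sig = dict(zip(de_hybrid_vs_paternal["gene_id"],
                      de_hybrid_vs_paternal["significant"]))
    rows = []
    for gene_id in de_parents["gene_id"]:
        if gene_id not in hm_sig or gene_id not in hp_sig:
            continue
        call = classify_inheritance(
            bool(pd_sig[gene_id]), bool(hm_sig[gene_id]),
            bool(hp_sig[gene_id]),
            float(norm_counts.loc[gene_id, list(hybrid_samples)].mean()),
            float(norm_counts.loc[gene_id, list(maternal_samples)].mean()),
            float(norm_counts.loc[gene_id, list(paternal_samples)].mean()),
            gene_id=gene_id, cross_id=cross_id, stage=stage,
            maternal_population=maternal_population,
            paternal_population=paternal_population)
        rows.append((call.gene_id, call.cross_id, call.stage, call.mode,
                     call.dominant_toward))
    return pd.DataFrame(rows, columns=[
        "gene_id", "cross_id", "stage", "mode", "dominant_toward"])
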