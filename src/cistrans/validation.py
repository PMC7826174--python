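"""Brute-force reference implementations and self-check experiments.

Every function here recomputes a quantity the package produces through an
independent route — exhaustive enumeration, all-pairs scanning, or
Monte-Carlo under a known null — so calibration and oracle-equivalence can
be asserted end to end.  The reference implementations deliberately avoid
the code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import FilterConfig, SimConfig
from . import diffexpr, popgen, annotation, ase as ase_mod, motifs
from .formats_io import PWM, GeneModel
from .regmech import trans_contribution_test


# ---------------------------------------------------------------------------
# reference implementations


def fisher_exact_reference(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact big-integer enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= p_obs:
            total += pk
    return float(total)


def bh_stepup_reference(ps) -> np.ndarray:
    """Benjamini-Hochberg from the definition: min_{k>=i} m*p_(k)/k."""
    ps = np.asarray(ps, dtype=float)
    m = ps.size
    order = np.argsort(ps, kind="stable")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * ps[i] / rank)
        out[i] = running
    return out


def pwm_hits_reference(sequence: str, pwm: PWM, threshold: float) -> set:
    """Window-by-window rescan of both strands."""
    lom = motifs._log_odds(pwm)
    smin = sum(min(lom[:, j]) for j in range(pwm.length))
    smax = sum(max(lom[:, j]) for j in range(pwm.length))
    bases = "ACGT"
    hits = set()
    for strand in "+-":
        seq = (sequence if strand == "+"
               else motifs.reverse_complement(sequence))
        for off in range(len(seq) - pwm.length + 1):
            window = seq[off:off + pwm.length]
            if any(b not in bases for b in window):
                continue
            score = sum(lom[bases.index(b), j]
                        for j, b in enumerate(window))
            rel = (score - smin) / (smax - smin)
            if rel >= threshold:
                fwd = (off if strand == "+"
                       else len(seq) - pwm.length - off)
                hits.add((fwd, strand))
    return hits


def interval_links_reference(variants, genes, window_bp) -> set:
    """All-pairs interval intersection."""
    out = set()
    for vid, _, scaf, vs, ve in variants:
        for g in genes:
            if g.scaffold != scaf:
                continue
            s, e = g.span
            if ve >= s - window_bp and vs <= e + window_bp:
                out.add((vid, g.gene_id))
    return out


# ---------------------------------------------------------------------------
# oracle-equivalence experiments


def fisher_max_discrepancy(n_tables: int = 1000, seed: int = 0,
                           max_total: int = 500) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        n = int(rng.integers(4, max_total + 1))
        cuts = sorted(rng.integers(0, n + 1, size=3))
        a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
        d = n - a - b - c
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        p1 = trans_contribution_test(a, b, c, d)
        p2 = fisher_exact_reference(a, b, c, d)
        worst = max(worst, abs(p1 - p2))
    return worst


def bh_max_discrepancy(n_vectors: int = 1000, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 60))
        ps = rng.uniform(0, 1, size=m)
        worst = max(worst, float(np.max(np.abs(
            diffexpr.bh_adjust(ps) - bh_stepup_reference(ps)))))
    return worst


def pwm_scan_mismatches(n_pairs: int = 100, seed: int = 0) -> int:
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_pairs):
        L = int(rng.integers(4, 10))
        seq = "".join(rng.choice(list("ACGT"), size=41))
        probs = rng.dirichlet(np.ones(4) * 0.5, size=L).T
        pwm = PWM("Mx", "rand", probs)
        thr = float(rng.uniform(0.6, 0.95))
        got = {(h.offset, h.strand)
               for h in motifs.pwm_relative_scores(seq, pwm, thr)}
        if got != pwm_hits_reference(seq, pwm, thr):
            bad += 1
    return bad


def interval_mismatches(n_instances: int = 100, seed: int = 0) -> int:
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_instances):
        genes = []
        for k, s in enumerate(rng.integers(1000, 200_000, size=8)):
            start = int(s)
            end = start + int(rng.integers(500, 3000))
            mid = (start + end) // 2
            genes.append(GeneModel(f"g{k}", "s", "+",
                                   [(start, mid - 1), (mid, end)]))
        variants = []
        for k in range(15):
            start = int(rng.integers(1, 210_000))
            end = start + (0 if rng.random() < 0.5
                           else int(rng.integers(1, 2000)))
            variants.append((f"v{k}", "SNP", "s", start, end))
        w = int(rng.choice([2000, 10_000, 20_000]))
        got = {(l.variant_id, l.gene_id) for l in
               annotation.associate_variants_with_genes(variants, genes, w)}
        if got != interval_links_reference(variants, genes, w):
            bad += 1
    return bad


# ---------------------------------------------------------------------------
# statistical calibration experiments


def fst_fixation_mismatches(n_configs: int = 10_000, seed: int = 0) -> int:
    """theta-hat = 1 iff genotype-level fixation, over random
    configurations with at least two called genotypes per population."""
    rng = np.random.default_rng(seed)
    bad = 0
    done = 0
    while done < n_configs:
        n1, n2 = rng.integers(2, 9, size=2)
        gt = np.concatenate([rng.integers(-1, 3, size=n1),
                             rng.integers(-1, 3, size=n2)]).astype(np.int8)
        if (gt[:n1] != -1).sum() < 2 or (gt[n1:] != -1).sum() < 2:
            continue
        done += 1
        from .formats_io import GenotypeMatrix
        import pandas as pd
        sites = pd.DataFrame({"scaffold": ["s"], "position": [100],
                              "ref": ["A"], "alt": ["G"]})
        samples = [f"x{i}" for i in range(n1 + n2)]
        pops = {s: ("p1" if i < n1 else "p2")
                for i, s in enumerate(samples)}
        m = GenotypeMatrix(sites, gt[None, :],
                           np.full((1, n1 + n2), 99.0), samples, pops)
        d = popgen.wc_fst_site(None, matrix=m, index=0)
        c1 = [g for g in gt[:n1] if g != -1]
        c2 = [g for g in gt[n1:] if g != -1]
        fixed = ((all(g == 0 for g in c1) and all(g == 2 for g in c2))
                 or (all(g == 2 for g in c1) and all(g == 0 for g in c2)))
        theta_one = np.isfinite(d.fst) and np.isclose(d.fst, 1.0)
        if fixed != theta_one or fixed != d.is_fixed:
            bad += 1
    return bad


def ase_null_false_positive_rate(n_genes: int = 2000, n_sims: int = 10_000,
                                 seed: int = 0, alpha: float = 0.05) -> float:
    """Fraction of balanced (50:50, rho = 0) genes called significant."""
    rng = np.random.default_rng(seed)
    hits = 0
    for g in range(n_genes):
        k = int(rng.integers(2, 7))
        totals = rng.poisson(100.0, size=k)
        mat = rng.binomial(totals, 0.5)
        res = ase_mod.gene_ase_test(
            mat, totals - mat, n_sims=n_sims,
            rng=np.random.default_rng(rng.integers(2 ** 63)),
            min_snv_coverage=10, alpha=alpha)
        if res is not None and res.significant:
            hits += 1
    return hits / n_genes


def de_null_significant_fraction(n_seeds: int = 10, n_genes: int = 2000,
                                 seed: int = 0) -> float:
    """Mean fraction of genes at padj < 0.01 when both groups share one
    negative-binomial law (n = 6 vs 6)."""
    rng = np.random.default_rng(seed)
    r = 1 / 0.05
    fractions = []
    for _ in range(n_seeds):
        mat = rng.negative_binomial(r, r / (r + 150), size=(n_genes, 12))
        c = pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)],
                         columns=[f"s{i}" for i in range(12)])
        res = diffexpr.nb_wald_de(c, ["a"] * 6 + ["b"] * 6, fdr=0.01)
        fractions.append(res["significant"].mean())
    return float(np.mean(fractions))


def de_power_fraction(n_genes: int = 500, seed: int = 0) -> float:
    """Fraction of genes with a planted 2-fold change (dispersion 0.1,
    mean 200, n = 8 vs 10) detected at padj < 0.01."""
    rng = np.random.default_rng(seed)
    r = 1 / 0.1
    m1 = rng.negative_binomial(r, r / (r + 200), size=(n_genes, 8))
    m2 = rng.negative_binomial(r, r / (r + 400), size=(n_genes, 10))
    c = pd.DataFrame(np.hstack([m1, m2]),
                     index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{i}" for i in range(18)])
    sf = pd.Series(1.0, index=c.columns)
    res = diffexpr.nb_wald_de(c, ["a"] * 8 + ["b"] * 10, sf, fdr=0.01)
    return float(res["significant"].mean())


# ---------------------------------------------------------------------------
# recovery experiments


RECOVERY_FRACTIONS = {"conserved": 0.90, "cis": 0.02, "trans": 0.04,
                      "cis_plus_trans": 0.02, "cis_times_trans": 0.02}


def regime_recovery(seed: int = 1, n_genes: int = 2000) -> dict:
    """Planted-regime recovery under the reference study conditions:
    |effect| = 1.5 log2, 100x SNV coverage, 6 vs 6 purebreds, 3 hybrids,
    one cross and stage, ASE test at 10,000 simulations."""
    from . import pipeline as pl

    cfg = {
        "seed": int(seed),
        "synthetic": {
            "n_genes": int(n_genes),
            "regime_fractions": RECOVERY_FRACTIONS,
            "n_crosses": 1, "stages": ["2dpf"],
            "n_per_group": {"2dpf": [6, 6, 3]},
            "n_background_svs": 200,
            "seed": int(seed),
        },
        "filters": {"n_ase_sims": 10_000},
    }
    import tempfile
    with tempfile.TemporaryDirectory() as tmp:
        res = pl.run_full_analysis(cfg=cfg, outdir=tmp)
        truth = res.table("truth")
        reg = res.table("regulatory_calls")
    m = reg.merge(truth, on="gene_id")
    divergent = m["category"].isin(
        ["cis", "trans", "cis_x_trans", "cis_plus_trans"])
    out = {}
    for regime in ("cis", "trans"):
        sub = m[m["regime"] == regime]
        out[f"{regime}_recovery"] = float(
            (sub["category"] == regime).mean())
        out[f"n_{regime}"] = int(len(sub))
    cons = m["regime"] == "conserved"
    out["conserved_divergent"] = float(divergent[cons].mean())
    out["n_conserved"] = int(cons.sum())
    return out


def end_to_end_candidates(seed: int = 1, n_genes: int = 600,
                          n_svs_total: int = 80_012) -> dict:
    """Paper-shaped end-to-end fixture: 157 fixed SNPs and 87 fixed
    deletions among ``n_svs_total`` SVs, two planted cis genes each within
    10 kb of exactly one fixed variant."""
    from . import pipeline as pl

    cfg = {
        "seed": int(seed),
        "synthetic": {
            "n_genes": int(n_genes),
            "n_fixed_snps": 157,
            "n_fixed_deletions": 87,
            "n_background_svs": int(n_svs_total) - 87,
            "n_crosses": 1, "stages": ["2dpf"],
            "n_per_group": {"2dpf": [6, 6, 3]},
            "seed": int(seed),
        },
        "filters": {"n_ase_sims": 10_000},
    }
    import tempfile
    with tempfile.TemporaryDirectory() as tmp:
        res = pl.run_full_analysis(cfg=cfg, outdir=tmp)
        truth = res.table("truth")
        report = res.table("candidate_report")
        n_fixed_snps = len(res.table("fixed_snps"))
        n_fixed_svs = len(res.table("fixed_svs"))
    planted = set(truth[(truth["regime"] == "cis")
                        & truth["linked_variant"].isin(
                            ["fixed_snp_candidate",
                             "fixed_del_candidate"])]["gene_id"])
    found = set(report["gene_id"])
    return {
        "n_fixed_snps": n_fixed_snps,
        "n_fixed_deletions": n_fixed_svs,
        "n_candidates": len(found),
        "planted_recovered": len(found & planted),
        "false_candidates": len(found - planted),
        "n_svs_total": int(n_svs_total),
    }


def worked_micro_examples() -> dict:
    """The in-text association distances and exon-context call, reproduced
    on hand-built fixtures."""
    g_del = GeneModel("dync2li1-like", "scaf43", "+",
                      [(100_000, 101_000), (107_000, 108_000)])
    d_end = 100_000 - 7384
    links_del = annotation.associate_variants_with_genes(
        [("del91", "DEL", "scaf43", d_end - 90, d_end)], [g_del], 10_000)
    g_snp = GeneModel("pycr3-like", "scaf16", "+",
                      [(50_000, 51_000), (55_000, 56_000)])
    pos = 56_000 + 1808
    links_snp = annotation.associate_variants_with_genes(
        [("snpAC", "SNP", "scaf16", pos, pos)], [g_snp], 10_000)
    boundary = annotation.associate_variants_with_genes(
        [("far", "SNP", "scaf16", 56_000 + 10_001, 56_000 + 10_001)],
        [g_snp], 10_000)
    exons = [(1000 + i * 2000, 1400 + i * 2000) for i in range(6)]
    g_ex = GeneModel("gpa33-like", "s", "+", exons)
    ex5 = exons[4]
    label, contained = annotation.variant_context(
        "s", ex5[0] - 400, ex5[1] + 456, [g_ex])
    return {
        "deletion_distance": links_del[0].distance if links_del else None,
        "snp_distance": links_snp[0].distance if links_snp else None,
        "beyond_window_linked": len(boundary),
        "exon_deletion_context": label,
        "contained_exon_index": contained[0][1] if contained else None,
    }
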