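"""Synthetic two-species cross datasets with planted ground truth.

The generator emulates the study design end-to-end: a genotype panel for two
recently diverged populations ("A", the molluscivore analogue, and "B", the
scale-eater analogue) with a controllable number of fixed and highly
differentiated SNPs; per-comparison structural-variant call sets sharing a
set of deletions fixed in population B; negative-binomial expression counts
for purebred and F1-hybrid offspring under planted regulatory regimes; and
beta-binomial allelic counts at informative heterozygous SNVs in hybrids.

Generative model for one gene with cis effect c and trans effect t (log2,
population B relative to A): purebred A mean mu, purebred B mean
mu * 2^(c+t); in the hybrid the two alleles share a midparent trans
environment, so the A-allele mean is (mu/2) * 2^(t/2) and the B-allele mean
(mu/2) * 2^c * 2^(t/2).  The hybrid maternal-allele read fraction at an
informative SNV is therefore 2^c/(1+2^c) when the mother is from B and
1/(1+2^c) when from A.  All counts are negative binomial with a common
dispersion and per-sample library-size factors; allelic counts are
beta-binomial around the allele fraction.

All randomness flows from ``SimConfig.seed``; the same seed reproduces the
dataset byte-for-byte when serialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import yaml

from .config import SimConfig, REGIMES
from .formats_io import (GenotypeMatrix, SVCallSet, GeneModel,
                         HOM_REF, HET, HOM_ALT,
                         write_genotype_matrix_vcf, write_sv_call_set_vcf,
                         write_gene_models_gff3, write_count_matrix,
                         write_sample_metadata, write_allele_counts)

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticDataset:
    config: SimConfig
    genotypes: GenotypeMatrix
    sv_call_sets: list
    gene_models: list
    counts: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame
    allele_counts: pd.DataFrame
    truth: pd.DataFrame
    parent_f1_genotypes: dict  # cross_id -> DataFrame
    variant_sequences: pd.DataFrame  # candidate variants with flank sequence
    crosses: pd.DataFrame  # cross_id, maternal_population, paternal_population


# ---------------------------------------------------------------------------
# single-gene generative ops


def regime_effects(regime: str, config: SimConfig,
                   rng: np.random.Generator) -> tuple:
    """Planted (cis, trans) log2 effects for one gene of the given regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    sign = 1.0 if rng.random() < 0.5 else -1.0
    c, t = config.cis_effect_log2, config.trans_effect_log2
    if regime == "conserved":
        return 0.0, 0.0
    if regime == "cis":
        return sign * c, 0.0
    if regime == "trans":
        return 0.0, sign * t
    if regime == "cis_plus_trans":
        return sign * c, sign * t
    # cis_times_trans: opposing signs
    return sign * c, -sign * t


def regime_means(mu: float, cis_log2: float, trans_log2: float) -> dict:
    """Expected expression means implied by the planted effects."""
    if mu <= 0:
        raise ValueError("baseline mean must be positive")
    mean_a = mu
    mean_b = mu * 2.0 ** (cis_log2 + trans_log2)
    allele_a = 0.5 * mu * 2.0 ** (trans_log2 / 2.0)
    allele_b = allele_a * 2.0 ** cis_log2
    return {"A": mean_a, "B": mean_b,
            "hybrid_allele_A": allele_a, "hybrid_allele_B": allele_b,
            "hybrid_total": allele_a + allele_b}


def _nb_draw(mean, dispersion: float, rng: np.random.Generator):
    """Negative-binomial draw with mean/dispersion parameterization."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("negative-binomial mean must be positive")
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _beta_binomial(totals, p, rho: float, rng: np.random.Generator):
    totals = np.asarray(totals)
    if rho > 0:
        a = p * (1.0 / rho - 1.0)
        b = (1.0 - p) * (1.0 / rho - 1.0)
        ps = rng.beta(a, b, size=totals.shape)
        return rng.binomial(totals, ps)
    return rng.binomial(totals, p)


def simulate_gene_counts(regime: str, effects: tuple, config: SimConfig,
                         rng: np.random.Generator,
                         n_per_group: tuple = (6, 6, 3),
                         library_factors: tuple = None) -> dict:
    """Per-sample expression counts for one gene.

    Returns a dict with keys "A", "B", "hybrid" holding integer count
    arrays of sizes ``n_per_group``.  ``effects`` is (cis_log2, trans_log2);
    ``library_factors`` optionally fixes the per-sample factors (three
    arrays), otherwise they are drawn log-uniform from
    ``config.library_size_range``.
    """
    c, t = effects
    n_a, n_b, n_h = n_per_group
    mu = float(np.exp(rng.uniform(*np.log(config.mean_expression_range))))
    means = regime_means(mu, c, t)
    if library_factors is None:
        lo, hi = np.log(config.library_size_range)
        library_factors = tuple(np.exp(rng.uniform(lo, hi, size=n))
                                for n in (n_a, n_b, n_h))
    fa, fb, fh = library_factors
    return {
        "A": _nb_draw(means["A"] * np.asarray(fa), config.nb_dispersion, rng),
        "B": _nb_draw(means["B"] * np.asarray(fb), config.nb_dispersion, rng),
        "hybrid": _nb_draw(means["hybrid_total"] * np.asarray(fh),
                           config.nb_dispersion, rng),
    }


def simulate_allele_counts(cis_log2: float, n_snvs: int, n_hybrids: int,
                           config: SimConfig, rng: np.random.Generator,
                           maternal_is_b: bool = True) -> tuple:
    """Maternal/paternal read counts at each SNV for each hybrid.

    Per SNV, total coverage is Poisson(``snv_coverage_mean``) and the
    maternal count beta-binomial(total, p_maternal, ``bb_rho``) with
    p_maternal = 2^c/(1+2^c) for a B mother (1/(1+2^c) for an A mother).
    Returns (maternal, paternal) integer arrays of shape
    (n_hybrids, n_snvs).
    """
    ratio = 2.0 ** cis_log2
    p_mat = ratio / (1.0 + ratio) if maternal_is_b else 1.0 / (1.0 + ratio)
    totals = rng.poisson(config.snv_coverage_mean, size=(n_hybrids, n_snvs))
    mat = _beta_binomial(totals, p_mat, config.bb_rho, rng)
    return mat, totals - mat


# ---------------------------------------------------------------------------
# genome layout helpers


def _build_gene_models(config: SimConfig, rng: np.random.Generator) -> list:
    per_scaf = -(-config.n_genes // config.n_scaffolds)
    models = []
    for i in range(config.n_genes):
        scaf = f"scaffold_{i // per_scaf + 1}"
        slot = i % per_scaf
        start = 5001 + slot * config.gene_spacing_bp
        n_ex = int(rng.integers(2, 6))
        exons = []
        pos = start
        for k in range(n_ex):
            ex_len = int(rng.integers(120, 600))
            exons.append((pos, pos + ex_len - 1))
            pos += ex_len + int(rng.integers(300, 1500))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(f"gene{i + 1:05d}", scaf, strand, exons))
    return models


def _assign_regimes(config: SimConfig, rng: np.random.Generator) -> list:
    counts = {}
    remaining = config.n_genes
    fracs = dict(config.regime_fractions)
    for regime in ("cis", "trans", "cis_plus_trans", "cis_times_trans"):
        n = int(round(fracs.get(regime, 0.0) * config.n_genes))
        counts[regime] = n
        remaining -= n
    if remaining < 0:
        raise ValueError("regime fractions exceed the gene count")
    counts["conserved"] = remaining
    labels = []
    for regime, n in counts.items():
        labels.extend([regime] * n)
    labels = np.array(labels)
    rng.shuffle(labels)
    return [str(x) for x in labels]


def _expected_inheritance(regime: str) -> str:
    if regime == "conserved":
        return "undetermined"
    if regime == "cis_times_trans":
        return "overdominant"
    return "additive"


# ---------------------------------------------------------------------------
# the full dataset


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the complete synthetic experiment for ``config``.

    Plants ``n_fixed_snps`` alternately homozygous SNPs and
    ``n_fixed_deletions`` deletions fixed in population B, placing one fixed
    deletion 7,384 bp upstream of one cis-regime gene and one fixed SNP
    1,808 bp downstream of another (the two "top candidate" genes), and one
    fixed SNP within the near window of each of up to ten trans-regime genes;
    the remainder live in gene-free desert scaffolds.  Highly differentiated
    and background SNPs are drawn so that none is accidentally fixed.
    """
    rng = np.random.default_rng(config.seed)
    gene_models = _build_gene_models(config, rng)
    regimes = _assign_regimes(config, rng)

    cis_genes = [i for i, r in enumerate(regimes) if r == "cis"]
    trans_genes = [i for i, r in enumerate(regimes) if r == "trans"]

    # ----- effects and truth ----------------------------------------------
    effects = [regime_effects(r, config, rng) for r in regimes]

    # ----- genotype panel --------------------------------------------------
    n_pp = config.n_per_pop_genotypes
    samples = [f"A_ind{i + 1}" for i in range(n_pp)] + \
              [f"B_ind{i + 1}" for i in range(n_pp)]
    populations = {s: s.split("_")[0] for s in samples}
    a_cols = np.arange(n_pp)
    b_cols = np.arange(n_pp, 2 * n_pp)

    site_rows, site_gts = [], []

    def add_site(scaffold, pos, gts, ref=None, alt=None):
        if ref is None:
            ref, alt = [str(b) for b in rng.choice(BASES, 2, replace=False)]
        site_rows.append((scaffold, int(pos), ref, alt))
        site_gts.append(gts)

    def fixed_gts():
        g = np.empty(2 * n_pp, dtype=np.int8)
        g[a_cols] = HOM_REF
        g[b_cols] = HOM_ALT
        return g

    def non_fixed_gts(p_a, p_b):
        while True:
            g = np.empty(2 * n_pp, dtype=np.int8)
            g[a_cols] = rng.binomial(2, p_a, size=n_pp)
            g[b_cols] = rng.binomial(2, p_b, size=n_pp)
            a, b = g[a_cols], g[b_cols]
            fixed = ((np.all(a == HOM_REF) and np.all(b == HOM_ALT))
                     or (np.all(a == HOM_ALT) and np.all(b == HOM_REF)))
            alt_total = g.sum()
            maf = min(alt_total, 4 * n_pp - alt_total) / (4 * n_pp)
            if not fixed and maf >= 0.05:
                return g

    # candidate gene-linked fixed variants; candidates need room upstream
    # for the planted deletion and non-cis flanking genes so the 10 kb
    # window of each planted variant reaches exactly one cis gene
    def _candidate_ok(gi):
        if gene_models[gi].span[0] <= 7600:
            return False
        for nb in (gi - 1, gi + 1):
            if 0 <= nb < config.n_genes \
                    and gene_models[nb].scaffold == gene_models[gi].scaffold \
                    and regimes[nb] == "cis":
                return False
        return True

    eligible_cis = [gi for gi in cis_genes if _candidate_ok(gi)]
    if len(eligible_cis) < 2:
        eligible_cis = cis_genes
    n_linked_trans = min(10, len(trans_genes),
                         max(0, config.n_fixed_snps - 1))
    candidate_del_gene = eligible_cis[0] if len(eligible_cis) >= 1 else None
    candidate_snp_gene = eligible_cis[1] if len(eligible_cis) >= 2 else None
    if config.n_fixed_snps < 1:
        candidate_snp_gene = None
    if config.n_fixed_deletions < 1:
        candidate_del_gene = None

    n_desert_snps = config.n_fixed_snps
    if candidate_snp_gene is not None:
        gm = gene_models[candidate_snp_gene]
        # A-to-C transversion 1,808 bp downstream of the gene span
        add_site(gm.scaffold, gm.span[1] + 1808, fixed_gts(), "A", "C")
        n_desert_snps -= 1
    linked_trans = trans_genes[:n_linked_trans]
    for gi in linked_trans:
        gm = gene_models[gi]
        # 2-4 kb upstream keeps the SNP within 10 kb of this gene only
        add_site(gm.scaffold, max(1, gm.span[0] - int(rng.integers(2000, 4000))),
                 fixed_gts())
        n_desert_snps -= 1

    # desert scaffolds hold the remaining fixed, differentiated and
    # background SNPs plus the structural-variant background
    desert = "scaffold_desert_snp"
    pos = 1000
    for _ in range(n_desert_snps):
        add_site(desert, pos, fixed_gts())
        pos += 1000
    for _ in range(config.n_differentiated_snps):
        add_site(desert, pos, non_fixed_gts(0.08, 0.92))
        pos += 1000
    for _ in range(config.n_background_snps):
        p = rng.uniform(0.15, 0.85)
        add_site(desert, pos, non_fixed_gts(p, p))
        pos += 1000

    sites = pd.DataFrame(site_rows,
                         columns=["scaffold", "position", "ref", "alt"])
    gt_arr = np.vstack(site_gts).astype(np.int8)
    order = np.lexsort((sites["position"].to_numpy(),
                        sites["scaffold"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    gt_arr = gt_arr[order]
    gq_arr = np.full(gt_arr.shape, 99.0)
    genotypes = GenotypeMatrix(sites, gt_arr, gq_arr, samples, populations)

    # ----- structural-variant call sets -----------------------------------
    sv_rows = []  # scaffold, start, end, type, length, kind
    if candidate_del_gene is not None and config.n_fixed_deletions >= 1:
        gm = gene_models[candidate_del_gene]
        # 91 bp deletion ending 7,384 bp upstream of the gene span
        d_end = gm.span[0] - 7384
        sv_rows.append((gm.scaffold, d_end - 90, d_end, "DEL", 91, "fixed"))
    n_desert_fixed = config.n_fixed_deletions - len(sv_rows)
    sv_desert = "scaffold_desert_sv"
    pos = 10_000
    for _ in range(n_desert_fixed):
        length = int(rng.integers(55, 4704))
        sv_rows.append((sv_desert, pos, pos + length - 1, "DEL", length,
                        "fixed"))
        pos += 12_000
    bg_types = rng.choice(["DEL", "INS", "INV"], size=config.n_background_svs,
                          p=[0.7, 0.15, 0.15])
    for k in range(config.n_background_svs):
        length = int(rng.integers(50, 5001))
        sv_rows.append((sv_desert, pos, pos + length - 1, str(bg_types[k]),
                        length, "background"))
        pos += 12_000

    sv_df = pd.DataFrame(sv_rows, columns=["scaffold", "start", "end",
                                           "sv_type", "length", "kind"])
    n_sv = len(sv_df)
    fixed_mask = (sv_df["kind"] == "fixed").to_numpy()
    # genotypes shared across call sets (the same underlying variant)
    sv_gts = np.empty((n_sv, 2 * n_pp), dtype=np.int8)
    sv_gts[np.ix_(fixed_mask, a_cols)] = HOM_REF
    sv_gts[np.ix_(fixed_mask, b_cols)] = HOM_ALT
    bg_idx = np.nonzero(~fixed_mask)[0]
    bg = rng.binomial(2, 0.35, size=(bg_idx.size, 2 * n_pp)).astype(np.int8)
    a_part, b_part = bg[:, :n_pp], bg[:, n_pp:]
    # break accidental fixation under the carrier rule (one population all
    # reference, the other all alternate-carrying)
    a_ref = np.all(a_part == HOM_REF, axis=1)
    b_ref = np.all(b_part == HOM_REF, axis=1)
    a_carry = np.all(a_part >= HET, axis=1)
    b_carry = np.all(b_part >= HET, axis=1)
    bg[a_ref & b_carry, 0] = HET        # give population A a carrier
    bg[b_ref & a_carry, 0] = HOM_REF    # give population A a reference ind.
    sv_gts[bg_idx] = bg

    # a fraction of background SVs is private to a subset of call sets
    n_sets = config.n_sv_call_sets
    present = np.ones((n_sv, n_sets), dtype=bool)
    some_bg = bg_idx[rng.random(bg_idx.size) < 0.1]
    for ri in some_bg:
        drop = rng.integers(0, n_sets)
        present[ri, drop] = False

    call_sets = []
    for ci in range(n_sets):
        keep = np.nonzero(present[:, ci])[0]
        recs = sv_df.iloc[keep][["scaffold", "start", "end", "sv_type",
                                 "length"]].reset_index(drop=True).copy()
        if ci > 0:  # later call sets report slightly jittered breakpoints
            jitter = rng.integers(-5, 6, size=len(recs))
            recs["start"] = recs["start"] + jitter
            recs["end"] = recs["end"] + jitter
        call_sets.append(SVCallSet(f"callset_{ci + 1}", recs,
                                   sv_gts[keep].copy(), list(samples)))

    # ----- expression counts ----------------------------------------------
    crosses = []
    for k in range(config.n_crosses):
        cross_id = f"cross_{k + 1}"
        maternal = "B" if k % 2 == 0 else "A"
        paternal = "A" if maternal == "B" else "B"
        crosses.append((cross_id, maternal, paternal))
    crosses_df = pd.DataFrame(crosses, columns=[
        "cross_id", "maternal_population", "paternal_population"])

    mu = np.exp(rng.uniform(*np.log(config.mean_expression_range),
                            size=config.n_genes))
    cis_arr = np.array([e[0] for e in effects])
    trans_arr = np.array([e[1] for e in effects])
    mean_a = mu
    mean_b = mu * 2.0 ** (cis_arr + trans_arr)
    mean_h = 0.5 * mu * 2.0 ** (trans_arr / 2.0) * (1.0 + 2.0 ** cis_arr)

    gene_ids = [gm.gene_id for gm in gene_models]
    sample_ids, meta_rows = [], []
    count_cols = []
    lo, hi = np.log(config.library_size_range)
    for cross_id, mat_pop, pat_pop in crosses:
        for stage in config.stages:
            n_a, n_b, n_h = config.n_per_group[stage]
            for role, n, mean_vec, species in (
                    ("purebred_A", n_a, mean_a, "A"),
                    ("purebred_B", n_b, mean_b, "B"),
                    ("hybrid", n_h, mean_h, "F1")):
                for j in range(n):
                    sid = f"{cross_id}_{stage}_{role}_{j + 1}"
                    factor = float(np.exp(rng.uniform(lo, hi)))
                    counts = _nb_draw(mean_vec * factor,
                                      config.nb_dispersion, rng)
                    sample_ids.append(sid)
                    count_cols.append(counts)
                    meta_rows.append((sid, species, cross_id, stage, role,
                                      mat_pop, pat_pop))
    counts = pd.DataFrame(np.column_stack(count_cols), index=gene_ids,
                          columns=sample_ids)
    metadata = pd.DataFrame(meta_rows, columns=[
        "sample_id", "species", "cross", "stage", "role",
        "maternal_population", "paternal_population"])

    # ----- informative SNVs, parent/F1 genotypes, allelic counts ----------
    n_snvs = rng.integers(config.snv_per_gene_range[0],
                          config.snv_per_gene_range[1] + 1,
                          size=config.n_genes)
    snv_rows = []  # gene_index, scaffold, position, ref, alt
    for i, gm in enumerate(gene_models):
        placed = set()
        for _ in range(int(n_snvs[i])):
            ex = gm.exons[int(rng.integers(0, len(gm.exons)))]
            p = int(rng.integers(ex[0], ex[1] + 1))
            while p in placed:
                p = int(rng.integers(ex[0], ex[1] + 1))
            placed.add(p)
            ref, alt = [str(b) for b in rng.choice(BASES, 2, replace=False)]
            snv_rows.append((i, gm.scaffold, p, ref, alt))
    snv_df = pd.DataFrame(snv_rows, columns=["gene_index", "scaffold",
                                             "position", "ref", "alt"])

    parent_f1 = {}
    ac_rows = []
    hybrids_by_cross_stage = metadata[metadata["role"] == "hybrid"]
    for cross_id, mat_pop, pat_pop in crosses:
        # parents alternately homozygous at every informative SNV; the
        # maternal allele is ref or alt at random per site
        mother_is_ref = rng.random(len(snv_df)) < 0.5
        mother_gt = np.where(mother_is_ref, HOM_REF, HOM_ALT).astype(np.int8)
        father_gt = np.where(mother_is_ref, HOM_ALT, HOM_REF).astype(np.int8)
        f1_gt = np.full(len(snv_df), HET, dtype=np.int8)
        pf1 = snv_df[["scaffold", "position", "ref", "alt"]].copy()
        pf1["gene_id"] = [gene_ids[gi] for gi in snv_df["gene_index"]]
        pf1["mother_gt"] = mother_gt
        pf1["father_gt"] = father_gt
        pf1["f1_gt"] = f1_gt
        parent_f1[cross_id] = pf1

        maternal_is_b = mat_pop == "B"
        snv_gene_ids = np.array([gene_ids[gi] for gi in snv_df["gene_index"]])
        ratio = 2.0 ** cis_arr[snv_df["gene_index"].to_numpy()]
        p_mat = ratio / (1 + ratio) if maternal_is_b else 1.0 / (1 + ratio)
        for stage in config.stages:
            hyb = hybrids_by_cross_stage[
                (hybrids_by_cross_stage["cross"] == cross_id)
                & (hybrids_by_cross_stage["stage"] == stage)]
            for sid in hyb["sample_id"]:
                totals = rng.poisson(config.snv_coverage_mean,
                                     size=len(snv_df))
                mat_counts = _beta_binomial(totals, p_mat, config.bb_rho, rng)
                ac_rows.append(pd.DataFrame({
                    "sample_id": sid,
                    "gene_id": snv_gene_ids,
                    "scaffold": snv_df["scaffold"].to_numpy(),
                    "position": snv_df["position"].to_numpy(),
                    "maternal_count": mat_counts,
                    "paternal_count": totals - mat_counts,
                    "cross_id": cross_id,
                    "stage": stage,
                }))
    allele_counts = pd.concat(ac_rows, ignore_index=True)

    # ----- truth table -----------------------------------------------------
    linked_variant = {gi: "" for gi in range(config.n_genes)}
    linked_distance = {gi: np.nan for gi in range(config.n_genes)}
    if candidate_del_gene is not None and config.n_fixed_deletions >= 1:
        linked_variant[candidate_del_gene] = "fixed_del_candidate"
        linked_distance[candidate_del_gene] = -7384
    if candidate_snp_gene is not None:
        linked_variant[candidate_snp_gene] = "fixed_snp_candidate"
        linked_distance[candidate_snp_gene] = 1808
    for gi in linked_trans:
        linked_variant[gi] = "fixed_snp_near_trans"
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "regime": regimes,
        "cis_effect_log2": cis_arr,
        "trans_effect_log2": trans_arr,
        "expected_inheritance": [_expected_inheritance(r) for r in regimes],
        "linked_variant": [linked_variant[i] for i in range(config.n_genes)],
        "linked_distance": [linked_distance[i] for i in range(config.n_genes)],
    })

    # ----- flanking sequences for the candidate variants -------------------
    seq_rows = []
    if candidate_snp_gene is not None:
        flank_l = "".join(rng.choice(BASES, 20))
        flank_r = "".join(rng.choice(BASES, 20))
        seq_rows.append(("fixed_snp_candidate", "SNP",
                         flank_l + "A" + flank_r, "A", "C", 20))
    if candidate_del_gene is not None and config.n_fixed_deletions >= 1:
        flank_l = "".join(rng.choice(BASES, 20))
        flank_r = "".join(rng.choice(BASES, 20))
        deleted = "".join(rng.choice(BASES, 91))
        seq_rows.append(("fixed_del_candidate", "DEL",
                         flank_l + deleted + flank_r, deleted, "", 20))
    variant_sequences = pd.DataFrame(seq_rows, columns=[
        "variant_id", "variant_type", "reference_sequence", "ref_allele",
        "alt_allele", "variant_offset"])

    return SyntheticDataset(config, genotypes, call_sets, gene_models,
                            counts, metadata, allele_counts, truth,
                            parent_f1, variant_sequences, crosses_df)


# ---------------------------------------------------------------------------
# serialization


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Serialize every component in the plain-text dialects formats_io reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genotype_matrix_vcf(ds.genotypes, out / "genotypes.vcf")
    (out / "populations.tsv").write_text(
        "sample_id\tpopulation\n" + "".join(
            f"{s}\t{p}\n" for s, p in ds.genotypes.populations.items()))
    for cs in ds.sv_call_sets:
        write_sv_call_set_vcf(cs, out / f"sv_{cs.source_id}.vcf")
    write_gene_models_gff3(ds.gene_models, out / "genes.gff3")
    write_count_matrix(ds.counts, out / "counts.tsv")
    write_sample_metadata(ds.metadata, out / "metadata.tsv")
    write_allele_counts(ds.allele_counts, out / "allele_counts.tsv")
    ds.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    ds.crosses.to_csv(out / "crosses.tsv", sep="\t", index=False)
    ds.variant_sequences.to_csv(out / "variant_sequences.tsv", sep="\t",
                                index=False)
    for cross_id, pf1 in ds.parent_f1_genotypes.items():
        pf1.to_csv(out / f"parent_f1_{cross_id}.tsv", sep="\t", index=False)
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(ds.config.to_dict(), fh, sort_keys=True)
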