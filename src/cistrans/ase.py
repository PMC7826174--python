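"""Allele-specific expression: informative sites and the gene-level test.

The gene-level test mirrors a 1-sample MBASED analysis: SNVs within a gene
are pseudo-phased by majority vote (per SNV the "major" allele is the
parental allele with the higher count, ties resolved to maternal), the gene
major-allele frequency (MAF) aggregates major counts over used SNVs, and the
null distribution is simulated by redrawing each SNV's maternal count from a
beta-binomial(total, 0.5, rho) and re-applying the same pseudo-phasing.  The
empirical p-value is (1 + #{sim MAF >= observed}) / (1 + n_sims), so it can
never be exactly zero.  rho = 0 gives a binomial null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import HET, HOM_ALT, HOM_REF

logger = logging.getLogger(__name__)


@dataclass
class InformativeSite:
    scaffold: str
    position: int
    gene_id: str
    maternal_allele: str
    paternal_allele: str
    cross_id: str


@dataclass
class ASEResult:
    sample_id: str
    gene_id: str
    n_snvs: int
    maf: float  # aggregate major-allele frequency, in [0.5, 1]
    p: float  # empirical p, in (0, 1]
    significant: bool


def informative_sites(mother_genotypes: pd.DataFrame,
                      father_genotypes: pd.DataFrame,
                      f1_genotypes: pd.DataFrame,
                      gene_links: pd.DataFrame,
                      cross_id: str = "") -> tuple:
    """Sites alternately homozygous in the parents and het in the F1.

    Each genotype frame needs columns (scaffold, position, ref, alt, gt)
    with integer genotype codes; ``gene_links`` maps (scaffold, position) to
    gene_id.  Returns ``(sites, n_mendelian_inconsistent)`` where the second
    element counts parental alternate-homozygous sites at which the F1 is
    itself homozygous (excluded, diagnostic only).
    """
    key = ["scaffold", "position"]
    merged = (mother_genotypes.rename(columns={"gt": "mother_gt"})
              .merge(father_genotypes[key + ["gt"]]
                     .rename(columns={"gt": "father_gt"}), on=key)
              .merge(f1_genotypes[key + ["gt"]]
                     .rename(columns={"gt": "f1_gt"}), on=key)
              .merge(gene_links[key + ["gene_id"]], on=key))
    out = []
    n_inconsistent = 0
    for row in merged.itertuples():
        mg, fg, f1 = int(row.mother_gt), int(row.father_gt), int(row.f1_gt)
        alt_hom = {mg, fg} == {HOM_REF, HOM_ALT}
        if not alt_hom:
            continue
        if f1 != HET:
            n_inconsistent += 1
            continue
        maternal = row.ref if mg == HOM_REF else row.alt
        paternal = row.alt if mg == HOM_REF else row.ref
        out.append(InformativeSite(row.scaffold, int(row.position),
                                   row.gene_id, maternal, paternal, cross_id))
    if n_inconsistent:
        logger.info("informative_sites: %d Mendelian-inconsistent sites "
                    "excluded", n_inconsistent)
    return out, n_inconsistent


def _null_maf_draws(totals: np.ndarray, rho: float, n_sims: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Simulated null gene MAFs under beta-binomial(total, 0.5, rho)."""
    k = totals.shape[0]
    if rho > 0:
        ab = 0.5 * (1.0 / rho - 1.0)
        p = rng.beta(ab, ab, size=(n_sims, k))
        x = rng.binomial(totals[None, :], p)
    else:
        x = rng.binomial(totals[None, :], 0.5, size=(n_sims, k))
    major = np.maximum(x, totals[None, :] - x)
    return major.sum(axis=1) / totals.sum()


def gene_ase_test(maternal_counts, paternal_counts, *, rho: float = 0.0,
                  n_sims: int = 10_000, rng: np.random.Generator = None,
                  min_snv_coverage: int = 10, alpha: float = 0.05,
                  sample_id: str = "", gene_id: str = "") -> ASEResult:
    """Gene-level ASE test for one gene in one hybrid sample.

    ``maternal_counts``/``paternal_counts`` are per-SNV read counts; SNVs
    with total coverage below ``min_snv_coverage`` are dropped.  Returns
    ``None`` when no SNV passes coverage (gene untestable in this sample).
    """
    mat = np.asarray(maternal_counts, dtype=np.int64)
    pat = np.asarray(paternal_counts, dtype=np.int64)
    if mat.shape != pat.shape:
        raise ValueError("maternal/paternal count vectors differ in length")
    if np.any(mat < 0) or np.any(pat < 0):
        raise ValueError("allele counts must be nonnegative")
    totals = mat + pat
    keep = totals >= min_snv_coverage
    if not keep.any():
        return None
    mat, pat, totals = mat[keep], pat[keep], totals[keep]
    rng = rng if rng is not None else np.random.default_rng()
    # pseudo-phasing: per SNV the major allele is the higher count,
    # ties to maternal
    major = np.where(mat >= pat, mat, pat)
    obs_maf = major.sum() / totals.sum()
    sim_maf = _null_maf_draws(totals, rho, n_sims, rng)
    p = (1.0 + np.count_nonzero(sim_maf >= obs_maf)) / (1.0 + n_sims)
    return ASEResult(sample_id, gene_id, int(totals.size), float(obs_maf),
                     float(p), p < alpha)


def ase_table(allele_counts: pd.DataFrame, *, rho: float = 0.0,
              n_sims: int = 10_000, seed: int = 0,
              min_snv_coverage: int = 10, alpha: float = 0.05) -> pd.DataFrame:
    """Run the gene-level ASE test for every (sample, gene) in the table.

    ``allele_counts`` needs columns (sample_id, gene_id, maternal_count,
    paternal_count); untestable genes are omitted.  Deterministic for a
    given seed regardless of group iteration order (each group gets a
    child generator seeded from the parent stream).
    """
    results = []
    groups = allele_counts.groupby(["sample_id", "gene_id"], sort=True)
    master = np.random.default_rng(seed)
    for (sample_id, gene_id), sub in groups:
        rng = np.random.default_rng(master.integers(2 ** 63))
        res = gene_ase_test(
            sub["maternal_count"].to_numpy(),
            sub["paternal_count"].to_numpy(),
            rho=rho, n_sims=n_sims, rng=rng,
            min_snv_coverage=min_snv_coverage, alpha=alpha,
            sample_id=str(sample_id), gene_id=str(gene_id))
        if res is not None:
            results.append((res.sample_id, res.gene_id, res.n_snvs,
                            res.maf, res.p, res.significant))
    return pd.DataFrame(results, columns=[
        "sample_id", "gene_id", "n_snvs", "maf", "p", "significant"])
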