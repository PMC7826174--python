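"""Threshold and simulation configuration.

All analysis thresholds live in :class:`FilterConfig`; all generative
parameters of the synthetic-data module live in :class:`SimConfig`.  Both are
plain dataclasses so they can be round-tripped through YAML by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence


@dataclass
class FilterConfig:
    """Site filters and test thresholds used across the pipeline.

    Defaults follow the source study's filtering choices: biallelic SNPs with
    minor allele frequency >= 0.05, genotype quality > 20 (failing calls are
    masked, not dropped), call rate > 0.5; differential expression controlled
    at FDR 0.01; allele-specific expression called at alpha 0.05 from genes
    with >= 2 informative SNVs at >= 10x coverage and site depth >= 20;
    variant-gene windows of 10 kb (and 20 kb, the LD-decay distance); the
    genome-wide outlier thresholds Fst > 0.72 (99th percentile) and
    Dxy > 0.0083 (90th percentile).
    """

    min_maf: float = 0.05
    min_gq: float = 20.0
    min_call_rate: float = 0.5
    fdr_de: float = 0.01
    alpha_ase: float = 0.05
    alpha_t: float = 0.05
    min_informative_snvs: int = 2
    min_snv_coverage: int = 10
    min_site_depth: int = 20
    window_near: int = 10_000
    window_wide: int = 20_000
    fst_high: float = 0.72
    dxy_high: float = 0.0083
    n_ase_sims: int = 1_000_000
    # beta-binomial overdispersion of the simulated ASE null (0 = binomial)
    ase_rho: float = 0.0
    sv_breakpoint_tol: int = 50
    sv_min_reciprocal_overlap: float = 0.8
    # pseudocount added to ratio numerators/denominators in regmech
    ratio_pseudocount: float = 0.5
    # |log2 ratio| below this is treated as sign zero when comparing signs
    sign_deadzone: float = 0.05
    # parental entries of the trans-test 2x2 table: per-population "mean"
    # (rounded mean normalized count; variance-matched default) or "sum"
    fisher_parent_counts: str = "mean"
    # "did not show ASE" rule: "not_all" (complement of ASE-in-all-hybrids)
    # or "no_hybrid" (no hybrid individually significant)
    ase_none_rule: str = "not_all"
    # minimum analyzed sites for a divergence window to be reported
    min_window_sites: int = 1
    # multiallelic records: drop (default) or split into biallelic records
    split_multiallelic: bool = False
    # relative-profile-score threshold for motif hits
    motif_score_threshold: float = 0.95
    motif_flank_bp: int = 20

    def __post_init__(self) -> None:
        for name in ("min_maf", "min_call_rate", "fdr_de", "alpha_ase",
                     "alpha_t", "sv_min_reciprocal_overlap",
                     "motif_score_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("min_informative_snvs", "min_snv_coverage",
                     "min_site_depth", "window_near", "window_wide",
                     "n_ase_sims", "min_window_sites"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v!r}")
        if self.fisher_parent_counts not in ("mean", "sum"):
            raise ValueError("fisher_parent_counts must be 'mean' or 'sum'")
        if self.ase_none_rule not in ("not_all", "no_hybrid"):
            raise ValueError("ase_none_rule must be 'not_all' or 'no_hybrid'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        return cls(**dict(d))


#: regulatory regimes the generator can plant
REGIMES = ("conserved", "cis", "trans", "cis_plus_trans", "cis_times_trans")


def _default_regime_fractions() -> dict:
    return {
        "conserved": 0.90,
        "cis": 0.02,
        "trans": 0.04,
        "cis_plus_trans": 0.02,
        "cis_times_trans": 0.02,
    }


def _default_n_per_group() -> dict:
    # purebred sample sizes per stage follow the study design
    # (2 dpf: 6 vs 6, 8 dpf: 8 vs 10); 3 F1 hybrids per cross and stage
    return {"2dpf": (6, 6, 3), "8dpf": (8, 10, 3)}


@dataclass
class SimConfig:
    """Parameters of the synthetic two-species cross experiment.

    The generator emulates the study conditions: two recently diverged
    populations with a handful of fixed variants (157 SNPs, 87 deletions by
    default), negative-binomial expression counts for purebred and F1-hybrid
    offspring under planted regulatory regimes, and beta-binomial allelic
    counts at informative heterozygous sites in hybrids.  Dispersion,
    coverage and library-size parameters are not reported quantities of the
    source system; the defaults are documented modelling choices.
    """

    n_genes: int = 2000
    n_fixed_snps: int = 157
    n_differentiated_snps: int = 300
    n_background_snps: int = 2000
    n_fixed_deletions: int = 87
    n_background_svs: int = 1000
    regime_fractions: Mapping[str, float] = field(
        default_factory=_default_regime_fractions)
    cis_effect_log2: float = 1.5
    trans_effect_log2: float = 1.5
    nb_dispersion: float = 0.01
    bb_rho: float = 0.0
    mean_expression_range: tuple = (50.0, 500.0)
    snv_per_gene_range: tuple = (2, 6)
    snv_coverage_mean: float = 100.0
    library_size_range: tuple = (0.7, 1.4)
    n_per_group: Mapping[str, tuple] = field(default_factory=_default_n_per_group)
    n_crosses: int = 2
    stages: Sequence[str] = ("2dpf", "8dpf")
    # genotype panel used for the divergence scan (individuals per species)
    n_per_pop_genotypes: int = 8
    # SV call sets emulate per-comparison caller output files
    n_sv_call_sets: int = 8
    # genome layout
    n_scaffolds: int = 24
    gene_spacing_bp: int = 25_000
    seed: int = 0

    def __post_init__(self) -> None:
        total = 0.0
        for k, v in dict(self.regime_fractions).items():
            if k not in REGIMES:
                raise ValueError(f"unknown regime {k!r}")
            if v < 0:
                raise ValueError(f"regime fraction for {k!r} is negative")
            total += v
        if total > 1.0 + 1e-9:
            raise ValueError(f"regime fractions sum to {total} > 1")
        if not all(len(v) == 3 for v in self.n_per_group.values()):
            raise ValueError("n_per_group values must be (nA, nB, n_hybrid)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regime_fractions"] = dict(self.regime_fractions)
        d["n_per_group"] = {k: list(v) for k, v in self.n_per_group.items()}
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "n_per_group" in d:
            d["n_per_group"] = {k: tuple(v) for k, v in d["n_per_group"].items()}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "mean_expression_range" in d:
            d["mean_expression_range"] = tuple(d["mean_expression_range"])
        if "snv_per_gene_range" in d:
            d["snv_per_gene_range"] = tuple(d["snv_per_gene_range"])
        if "library_size_range" in d:
            d["library_size_range"] = tuple(d["library_size_range"])
        return cls(**d)
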