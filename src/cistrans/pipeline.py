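"""End-to-end orchestration: scan -> annotate -> DE -> ASE -> classify -> motifs.

The pipeline consumes either a synthetic dataset (generated from a seed) or
externally supplied files, runs every stage, writes each intermediate table
as TSV under the output directory, and distils a candidate report: genes
with at least one linked fixed variant, significant parental differential
expression in at least one stage, and a cis classification in at least one
cross/stage — the criterion that singles out candidate cis-acting variants.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import FilterConfig, SimConfig
from . import formats_io as fio
from . import popgen, annotation, diffexpr, ase as ase_mod, regmech, motifs
from .synthetic_data import SyntheticDataset, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    completed_stages: list = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def load_dataset(cfg: dict) -> SyntheticDataset:
    """Materialize the input dataset: synthetic (from seed) or from files."""
    if "synthetic" in cfg:
        overrides = dict(cfg.get("synthetic") or {})
        if "seed" not in overrides and "seed" in cfg:
            overrides["seed"] = int(cfg["seed"])
        sim = SimConfig.from_dict({**SimConfig().to_dict(), **overrides})
        return simulate_dataset(sim)
    inputs = cfg.get("inputs")
    if not inputs:
        raise ValueError("config must provide 'synthetic' or 'inputs'")
    required = ["genotypes_vcf", "populations_tsv", "gff3", "counts_tsv",
                "metadata_tsv", "allele_counts_tsv"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ValueError(f"missing inputs: {missing}")
    for key, value in inputs.items():
        paths = value if isinstance(value, list) else [value]
        for p in paths:
            if isinstance(p, str) and not Path(p).exists():
                raise FileNotFoundError(f"input {key}: {p} does not exist")
    pops = pd.read_csv(inputs["populations_tsv"], sep="\t")
    pop_map = dict(zip(pops["sample_id"], pops["population"]))
    filters = FilterConfig.from_dict(
        {**FilterConfig().to_dict(), **(cfg.get("filters") or {})})
    gm = fio.read_genotype_matrix(inputs["genotypes_vcf"], pop_map, filters)
    call_sets = [fio.read_sv_call_set(p) for p in inputs.get("sv_vcfs", [])]
    genes = fio.read_gene_models(inputs["gff3"])
    counts = fio.read_count_matrix(inputs["counts_tsv"])
    metadata = fio.read_sample_metadata(inputs["metadata_tsv"])
    allele_counts = fio.read_allele_counts(inputs["allele_counts_tsv"])
    if "cross_id" not in allele_counts.columns:
        sample_map = metadata.set_index("sample_id")
        allele_counts["cross_id"] = [
            sample_map.loc[s, "cross"] for s in allele_counts["sample_id"]]
        allele_counts["stage"] = [
            sample_map.loc[s, "stage"] for s in allele_counts["sample_id"]]
    crosses = (metadata[metadata["role"] == "hybrid"]
               [["cross", "maternal_population", "paternal_population"]]
               .drop_duplicates()
               .rename(columns={"cross": "cross_id"})
               .reset_index(drop=True))
    vseq = (pd.read_csv(inputs["variant_sequences_tsv"], sep="\t")
            if "variant_sequences_tsv" in inputs else
            pd.DataFrame(columns=["variant_id", "variant_type",
                                  "reference_sequence", "ref_allele",
                                  "alt_allele", "variant_offset"]))
    return SyntheticDataset(
        config=None, genotypes=gm, sv_call_sets=call_sets, gene_models=genes,
        counts=counts, metadata=metadata, allele_counts=allele_counts,
        truth=None, parent_f1_genotypes={}, variant_sequences=vseq,
        crosses=crosses)


# ---------------------------------------------------------------------------
# stages


def stage_scan(ds: SyntheticDataset, filters: FilterConfig) -> dict:
    out = {}
    out["site_divergence"] = popgen.site_divergence_table(ds.genotypes)
    fixed = popgen.detect_fixed_snps(ds.genotypes)
    out["fixed_snps"] = pd.DataFrame(
        [(s.scaffold, s.position, s.fst, s.p1, s.p2) for s in fixed],
        columns=["scaffold", "position", "fst", "p1", "p2"])
    for label, size in (("near", filters.window_near),
                        ("wide", filters.window_wide)):
        wins = popgen.window_divergence(
            ds.genotypes, window_bp=size, min_sites=filters.min_window_sites)
        out[f"windows_{label}"] = popgen.windows_to_frame(wins)
    if ds.sv_call_sets:
        pops = ds.genotypes.populations
        fixed_svs = popgen.fixed_structural_variants(
            ds.sv_call_sets, pops, filters)
    else:
        fixed_svs = []
    out["fixed_svs"] = popgen.fixed_svs_to_frame(fixed_svs)
    return out


def stage_annotate(scan_tables: dict, ds: SyntheticDataset,
                   filters: FilterConfig) -> dict:
    variants = []
    for row in scan_tables["fixed_snps"].itertuples():
        variants.append((f"snp_{row.scaffold}_{row.position}", "SNP",
                         row.scaffold, int(row.position), int(row.position)))
    for row in scan_tables["fixed_svs"].itertuples():
        variants.append((f"sv_{row.scaffold}_{row.start}", row.type,
                         row.scaffold, int(row.start), int(row.end)))
    links = annotation.associate_variants_with_genes(
        variants, ds.gene_models, filters.window_near)
    frame = annotation.links_to_frame(links)
    contexts = []
    for vid, vtype, scaf, start, end in variants:
        label, contained = annotation.variant_context(
            scaf, start, end, ds.gene_models, filters.window_near)
        contexts.append((vid, vtype, scaf, start, end, label,
                         ";".join(f"{g}:{k}" for g, k in contained)))
    ctx = pd.DataFrame(contexts, columns=[
        "variant_id", "variant_type", "scaffold", "start", "end",
        "context", "contained_exons"])
    return {"variant_gene_links": frame, "variant_context": ctx}


def _group_samples(metadata: pd.DataFrame, cross_id: str, stage: str) -> dict:
    sub = metadata[(metadata["cross"] == cross_id)
                   & (metadata["stage"] == stage)]
    return {
        "A": sub[sub["role"] == "purebred_A"]["sample_id"].tolist(),
        "B": sub[sub["role"] == "purebred_B"]["sample_id"].tolist(),
        "hybrid": sub[sub["role"] == "hybrid"]["sample_id"].tolist(),
    }


def stage_de(ds: SyntheticDataset, filters: FilterConfig) -> dict:
    """All four DE contrasts for every cross and stage."""
    de_tables = {}
    norm = {}
    for cross in ds.crosses.itertuples():
        for stage in sorted(ds.metadata["stage"].unique()):
            groups = _group_samples(ds.metadata, cross.cross_id, stage)
            if not groups["A"] or not groups["B"]:
                continue
            cols = groups["A"] + groups["B"] + groups["hybrid"]
            counts = ds.counts[cols]
            sf = diffexpr.median_ratio_size_factors(counts)
            norm[(cross.cross_id, stage)] = counts / sf
            contrasts = {
                "parents": (groups["A"], groups["B"]),
                "hybrid_vs_A": (groups["A"], groups["hybrid"]),
                "hybrid_vs_B": (groups["B"], groups["hybrid"]),
                "hybrid_vs_parents": (groups["A"] + groups["B"],
                                      groups["hybrid"]),
            }
            for name, (g1, g2) in contrasts.items():
                if len(g1) < 2 or len(g2) < 2:
                    continue
                labels = ["g1"] * len(g1) + ["g2"] * len(g2)
                res = diffexpr.nb_wald_de(ds.counts[g1 + g2], labels,
                                          sf.reindex(g1 + g2),
                                          fdr=filters.fdr_de)
                de_tables[(cross.cross_id, stage, name)] = res
    rows = []
    for (cross_id, stage, name), res in de_tables.items():
        r = res.copy()
        r.insert(0, "contrast", name)
        r.insert(0, "stage", stage)
        r.insert(0, "cross_id", cross_id)
        rows.append(r)
    table = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame())
    return {"de_results": table, "_de_tables": de_tables, "_norm": norm}


def stage_ase(ds: SyntheticDataset, filters: FilterConfig,
              seed: int) -> dict:
    ac = ds.allele_counts
    deep = ac[(ac["maternal_count"] + ac["paternal_count"])
              >= filters.min_site_depth]
    table = ase_mod.ase_table(
        deep, rho=filters.ase_rho, n_sims=filters.n_ase_sims, seed=seed,
        min_snv_coverage=filters.min_snv_coverage, alpha=filters.alpha_ase)
    sample_map = ds.metadata.set_index("sample_id")
    table["cross_id"] = [sample_map.loc[s, "cross"] for s in table["sample_id"]]
    table["stage"] = [sample_map.loc[s, "stage"] for s in table["sample_id"]]
    return {"ase_results": table}


def stage_classify(ds: SyntheticDataset, de_stage: dict, ase_tables: dict,
                   filters: FilterConfig) -> dict:
    reg_rows, inh_rows = [], []
    ase_results = ase_tables["ase_results"]
    for cross in ds.crosses.itertuples():
        mat_pop, pat_pop = cross.maternal_population, cross.paternal_population
        for stage in sorted(ds.metadata["stage"].unique()):
            key = (cross.cross_id, stage, "parents")
            if key not in de_stage["_de_tables"]:
                continue
            groups = _group_samples(ds.metadata, cross.cross_id, stage)
            norm = de_stage["_norm"][(cross.cross_id, stage)]
            maternal_samples = groups[mat_pop]
            paternal_samples = groups[pat_pop]
            ac = ds.allele_counts
            ac_sub = ac[(ac["cross_id"] == cross.cross_id)
                        & (ac["stage"] == stage)]
            ase_sub = ase_results[
                (ase_results["cross_id"] == cross.cross_id)
                & (ase_results["stage"] == stage)]
            de_parents = de_stage["_de_tables"][key]
            reg = regmech.regulatory_calls(
                list(ds.counts.index), ac_sub, ase_sub, de_parents, norm,
                maternal_samples, paternal_samples, groups["hybrid"],
                cross.cross_id, stage, filters)
            reg_rows.append(reg)
            de_hm = de_stage["_de_tables"].get(
                (cross.cross_id, stage,
                 "hybrid_vs_A" if mat_pop == "A" else "hybrid_vs_B"))
            de_hp = de_stage["_de_tables"].get(
                (cross.cross_id, stage,
                 "hybrid_vs_A" if pat_pop == "A" else "hybrid_vs_B"))
            if de_hm is not None and de_hp is not None:
                inh = regmech.inheritance_calls(
                    de_parents, de_hm, de_hp, norm,
                    maternal_samples, paternal_samples, groups["hybrid"],
                    cross.cross_id, stage, mat_pop, pat_pop)
                inh_rows.append(inh)
    reg_table = pd.concat(reg_rows, ignore_index=True) if reg_rows else \
        pd.DataFrame(columns=["gene_id", "cross_id", "stage", "category"])
    inh_table = pd.concat(inh_rows, ignore_index=True) if inh_rows else \
        pd.DataFrame(columns=["gene_id", "cross_id", "stage", "mode"])
    return {"regulatory_calls": reg_table, "inheritance_calls": inh_table}


def stage_motifs(ds: SyntheticDataset, pwms, filters: FilterConfig) -> dict:
    rows = []
    for v in ds.variant_sequences.itertuples():
        ref_seq, alt_seq, start, ref_end, alt_end = \
            motifs.build_allele_sequences(
                v.reference_sequence, int(v.variant_offset),
                v.ref_allele, "" if pd.isna(v.alt_allele) else v.alt_allele,
                filters.motif_flank_bp)
        for res in motifs.allele_motif_comparison(
                ref_seq, alt_seq, start, ref_end, alt_end, pwms,
                filters.motif_score_threshold):
            rows.append((v.variant_id, res["matrix_id"], res["name"],
                         res["status"], res["best_score_ref"],
                         res["best_score_alt"]))
    return {"motif_changes": pd.DataFrame(rows, columns=[
        "variant_id", "matrix_id", "name", "status",
        "best_score_ref", "best_score_alt"])}


def build_candidate_report(links: pd.DataFrame, de_results: pd.DataFrame,
                           regulatory: pd.DataFrame,
                           inheritance: pd.DataFrame,
                           motif_changes: pd.DataFrame) -> pd.DataFrame:
    """Top candidates: fixed linked variant + DE (any stage) + cis call."""
    if links.empty or de_results.empty or regulatory.empty:
        return pd.DataFrame(columns=[
            "gene_id", "n_linked_fixed_variants", "de_stages",
            "cis_calls", "inheritance_modes", "motif_changes"])
    linked = links.groupby("gene_id").size()
    de_parents = de_results[de_results["contrast"] == "parents"]
    de_sig = de_parents[de_parents["significant"]]
    cis = regulatory[regulatory["category"] == "cis"]
    candidates = sorted(set(linked.index) & set(de_sig["gene_id"])
                        & set(cis["gene_id"]))
    rows = []
    for g in candidates:
        de_stages = sorted(de_sig[de_sig["gene_id"] == g]["stage"].unique())
        cis_keys = sorted(
            f"{r.cross_id}/{r.stage}" for r in
            cis[cis["gene_id"] == g].itertuples())
        modes = sorted(set(
            inheritance[inheritance["gene_id"] == g]["mode"])) \
            if not inheritance.empty else []
        gene_links = links[links["gene_id"] == g]
        changes = ";".join(sorted(set(
            motif_changes[motif_changes["status"] != "unchanged"]
            ["matrix_id"]))) if not motif_changes.empty else ""
        rows.append((g, int(linked[g]), ";".join(de_stages),
                     ";".join(cis_keys), ";".join(modes), changes))
    return pd.DataFrame(rows, columns=[
        "gene_id", "n_linked_fixed_variants", "de_stages", "cis_calls",
        "inheritance_modes", "motif_changes"])


# ---------------------------------------------------------------------------
# driver


def run_full_analysis(config_path=None, cfg: dict = None,
                      outdir=None) -> PipelineResult:
    """Run every stage from a YAML config (or a pre-parsed dict).

    Writes every intermediate table plus a manifest of completed stages to
    the output directory; reproducible from (inputs, config, seed).
    """
    if cfg is None:
        cfg = load_config(config_path)
    outdir = Path(outdir or cfg.get("outdir", "pipeline_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    filters = FilterConfig.from_dict(
        {**FilterConfig().to_dict(), **(cfg.get("filters") or {})})
    result = PipelineResult()

    def finish_stage(name, tables, t0):
        for tname, tbl in tables.items():
            if tname.startswith("_"):
                continue
            result.tables[tname] = tbl
            tbl.to_csv(outdir / f"{tname}.tsv", sep="\t", index=False)
        result.completed_stages.append(name)
        logger.info("stage %-10s done in %.1fs", name, time.time() - t0)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump({"completed_stages": result.completed_stages,
                       "seed": seed}, fh, indent=2)

    t0 = time.time()
    ds = load_dataset(cfg)
    if cfg.get("write_dataset"):
        write_dataset(ds, outdir / "dataset")
    if ds.truth is not None:
        result.tables["truth"] = ds.truth
        ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    result.completed_stages.append("load")

    scan = stage_scan(ds, filters)
    finish_stage("scan", scan, t0)

    t0 = time.time()
    ann = stage_annotate(scan, ds, filters)
    finish_stage("annotate", ann, t0)

    t0 = time.time()
    de = stage_de(ds, filters)
    finish_stage("de", de, t0)

    t0 = time.time()
    ase_tables = stage_ase(ds, filters, seed)
    finish_stage("ase", ase_tables, t0)

    t0 = time.time()
    classify = stage_classify(ds, de, ase_tables, filters)
    finish_stage("classify", classify, t0)

    t0 = time.time()
    pwms = []
    pfm = (cfg.get("inputs") or {}).get("pfm_file")
    if pfm:
        pwms = fio.read_jaspar_pfms(pfm)
    motif_tables = stage_motifs(ds, pwms, filters)
    finish_stage("motifs", motif_tables, t0)

    t0 = time.time()
    report = build_candidate_report(
        ann["variant_gene_links"], de["de_results"],
        classify["regulatory_calls"], classify["inheritance_calls"],
        motif_tables["motif_changes"])
    finish_stage("candidates", {"candidate_report": report}, t0)
    return result
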