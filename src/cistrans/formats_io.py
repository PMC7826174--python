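"""Readers and writers for the external formats, plus load-time site filters.

Genotypes are held as small integer codes (:data:`HOM_REF`, :data:`HET`,
:data:`HOM_ALT`, :data:`MISSING`) in sites x samples arrays.  VCF parsing goes
through cyvcf2, GFF3 through gffutils, JASPAR matrices through Bio.motifs;
writers emit the plain-text dialects those readers accept, so matrices
round-trip exactly.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_STRINGS = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}

SV_TYPES = ("DEL", "INS", "INV", "TRA", "CNV")


# ---------------------------------------------------------------------------
# containers


@dataclass
class VariantSite:
    """One biallelic SNP site with per-individual diploid calls."""

    scaffold: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray  # (n_samples,) int8 codes
    genotype_qualities: np.ndarray  # (n_samples,) float

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class GenotypeMatrix:
    """Biallelic sites x individuals with population labels."""

    sites: pd.DataFrame  # columns: scaffold, position, ref, alt
    genotypes: np.ndarray  # (n_sites, n_samples) int8
    qualities: np.ndarray  # (n_sites, n_samples) float
    samples: list
    populations: dict  # sample -> population label

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pop_columns(self, population: str) -> np.ndarray:
        """Column indices of the samples belonging to ``population``."""
        return np.array([i for i, s in enumerate(self.samples)
                         if self.populations[s] == population], dtype=int)

    def site(self, i: int) -> VariantSite:
        row = self.sites.iloc[i]
        return VariantSite(row["scaffold"], int(row["position"]),
                           row["ref"], row["alt"],
                           self.genotypes[i].copy(), self.qualities[i].copy())


@dataclass
class StructuralVariant:
    """A structural-variant record with a 1-based inclusive span."""

    scaffold: str
    start: int
    end: int
    sv_type: str
    length: int
    genotypes: dict  # sample -> genotype code
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type != "TRA" and self.end < self.start:
            raise ValueError("end < start for intrachromosomal SV")
        if self.length <= 0:
            raise ValueError("length must be > 0")


@dataclass
class SVCallSet:
    """All records of one caller output file, column-oriented."""

    source_id: str
    records: pd.DataFrame  # scaffold, start, end, sv_type, length
    genotypes: np.ndarray  # (n_records, n_samples) int8
    samples: list

    def __len__(self) -> int:
        return len(self.records)

    def record(self, i: int) -> StructuralVariant:
        r = self.records.iloc[i]
        return StructuralVariant(
            r["scaffold"], int(r["start"]), int(r["end"]), r["sv_type"],
            int(r["length"]),
            {s: int(g) for s, g in zip(self.samples, self.genotypes[i])},
            self.source_id)


@dataclass
class GeneModel:
    """A gene with sorted, non-overlapping exon intervals (1-based inclusive)."""

    gene_id: str
    scaffold: str
    strand: str
    exons: list  # [(start, end), ...] sorted ascending

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = _merge_sorted_exons(self.exons, self.gene_id)

    @property
    def span(self) -> tuple:
        """(first-exon start, last-exon end) in ascending genomic coordinates."""
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class PWM:
    """Position weight matrix: column-stochastic probabilities over A,C,G,T."""

    matrix_id: str
    name: str
    probabilities: np.ndarray  # (4, L)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[0] != 4:
            raise ValueError("probabilities must be a 4 x L matrix")
        if self.probabilities.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        colsums = self.probabilities.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[1]


def _merge_sorted_exons(exons, gene_id):
    exons = sorted((int(a), int(b)) for a, b in exons)
    merged = []
    for s, e in exons:
        if merged and s <= merged[-1][1]:
            logger.warning("gene %s: overlapping exons merged at %d", gene_id, s)
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# VCF: SNP genotype matrices


def read_genotype_matrix(vcf_path, population_labels: Mapping[str, str],
                         filters=None) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF, applying the load-time site filters.

    Per-genotype calls with GQ below ``filters.min_gq`` are masked to missing;
    sites are then kept only if call rate > ``filters.min_call_rate`` and
    pooled minor allele frequency >= ``filters.min_maf`` (computed over all
    called genotypes across populations).  Multiallelic records are dropped
    (or split when ``filters.split_multiallelic``); indels are ignored.
    """
    from .config import FilterConfig
    from cyvcf2 import VCF

    filters = filters or FilterConfig()
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in population_labels:
            raise ValueError(f"sample {s!r} has no population label")

    rows, gts, gqs = [], [], []
    n_multi = n_nonsnp = n_maf = n_rate = 0
    for rec in vcf:
        alts = rec.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1:
            if not filters.split_multiallelic:
                n_multi += 1
                continue
            alleles = list(enumerate(alts, start=1))
        else:
            alleles = [(1, alts[0])]
        if len(rec.REF) != 1:
            n_nonsnp += 1
            continue
        gt_types = _cyvcf2_gt_codes(rec)
        quals = np.asarray(rec.gt_quals, dtype=float)
        for alt_index, alt in alleles:
            if len(alt) != 1 or alt not in "ACGT":
                n_nonsnp += 1
                continue
            g = gt_types.copy() if len(alleles) > 1 else gt_types
            if len(alleles) > 1:
                g = _split_allele(rec, alt_index)
            g = g.copy()
            g[quals < filters.min_gq] = MISSING
            called = g != MISSING
            rate = called.mean() if len(g) else 0.0
            if rate <= filters.min_call_rate:
                n_rate += 1
                continue
            alt_count = (g[called] == HET).sum() + 2 * (g[called] == HOM_ALT).sum()
            af = alt_count / (2 * called.sum())
            maf = min(af, 1.0 - af)
            if maf < filters.min_maf:
                n_maf += 1
                continue
            rows.append((rec.CHROM, rec.POS, rec.REF, alt))
            gts.append(g)
            gqs.append(quals.copy())

    logger.info(
        "read_genotype_matrix: retained %d sites "
        "(dropped: %d multiallelic, %d non-SNP, %d MAF, %d call-rate)",
        len(rows), n_multi, n_nonsnp, n_maf, n_rate)
    sites = pd.DataFrame(rows, columns=["scaffold", "position", "ref", "alt"])
    gt_arr = (np.vstack(gts).astype(np.int8) if gts
              else np.empty((0, len(samples)), np.int8))
    gq_arr = (np.vstack(gqs) if gqs
              else np.empty((0, len(samples)), float))
    return GenotypeMatrix(sites, gt_arr, gq_arr, samples,
                          {s: population_labels[s] for s in samples})


def _cyvcf2_gt_codes(rec) -> np.ndarray:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    mapping = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)
    return mapping[np.asarray(rec.gt_types, dtype=int)]


def _split_allele(rec, alt_index) -> np.ndarray:
    """Genotype codes w.r.t. one alt allele of a multiallelic record."""
    out = np.empty(len(rec.genotypes), dtype=np.int8)
    for j, gt in enumerate(rec.genotypes):
        a, b = gt[0], gt[1]
        if a < 0 or b < 0:
            out[j] = MISSING
        else:
            n_alt = (a == alt_index) + (b == alt_index)
            out[j] = (HOM_REF, HET, HOM_ALT)[n_alt]
    return out


def write_genotype_matrix_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT:GQ)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaf in pd.unique(matrix.sites["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_sites):
            row = matrix.sites.iloc[i]
            cells = [
                f"{GT_STRINGS[int(g)]}:{int(q)}"
                for g, q in zip(matrix.genotypes[i], matrix.qualities[i])
            ]
            fh.write(f"{row['scaffold']}\t{int(row['position'])}\t.\t"
                     f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT:GQ\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# VCF: structural-variant call sets


def read_sv_call_set(vcf_path, source_id=None) -> SVCallSet:
    """Load an SV call set from a VCF with SVTYPE/END INFO keys."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, gts = [], []
    for rec in vcf:
        sv_type = rec.INFO.get("SVTYPE")
        if sv_type is None:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} has no SVTYPE")
        end = int(rec.INFO.get("END", rec.POS))
        length = abs(int(rec.INFO.get("SVLEN", end - rec.POS + 1)))
        rows.append((rec.CHROM, rec.POS, end, sv_type, length))
        gts.append(_cyvcf2_gt_codes(rec))
    records = pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "sv_type", "length"])
    gt_arr = (np.vstack(gts).astype(np.int8) if gts
              else np.empty((0, len(samples)), np.int8))
    sid = source_id if source_id is not None else Path(str(vcf_path)).stem
    return SVCallSet(sid, records, gt_arr, samples)


def write_sv_call_set_vcf(call_set: SVCallSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaf in pd.unique(call_set.records["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(call_set.samples) + "\n")
        recs = call_set.records
        for i in range(len(recs)):
            r = recs.iloc[i]
            info = (f"SVTYPE={r['sv_type']};END={int(r['end'])};"
                    f"SVLEN={int(r['length'])}")
            cells = [GT_STRINGS[int(g)] for g in call_set.genotypes[i]]
            fh.write(f"{r['scaffold']}\t{int(r['start'])}\t.\tN\t"
                     f"<{r['sv_type']}>\t.\tPASS\t{info}\tGT\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def read_gene_models(gff3_path) -> list:
    """Parse gene models (gene + exon features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", force=True,
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            exons.append((exon.start, exon.end))
        if not exons:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, exons))
    # orphan exons (no parent gene) are warned about and skipped
    for exon in db.features_of_type("exon"):
        parents = list(db.parents(exon, featuretype="gene"))
        if not parents:
            logger.warning("exon at %s:%d-%d has no parent gene; skipped",
                           exon.seqid, exon.start, exon.end)
    return models


def write_gene_models_gff3(models: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            start, end = gm.span
            fh.write(f"{gm.scaffold}\t.\tgene\t{start}\t{end}\t.\t"
                     f"{gm.strand}\t.\tID={gm.gene_id}\n")
            for k, (s, e) in enumerate(gm.exons, 1):
                fh.write(f"{gm.scaffold}\t.\texon\t{s}\t{e}\t.\t{gm.strand}\t."
                         f"\tID={gm.gene_id}.exon{k};Parent={gm.gene_id}\n")


# ---------------------------------------------------------------------------
# JASPAR position frequency matrices


def read_jaspar_pfms(source) -> list:
    """Parse JASPAR-format PFMs into PWMs (counts column-normalized).

    ``source`` may be a path or a file-like object.  A column summing to zero
    is an error.
    """
    from Bio import motifs as bio_motifs

    if hasattr(source, "read"):
        handle = source
        parsed = list(bio_motifs.parse(handle, "jaspar"))
    else:
        with open(source) as handle:
            parsed = list(bio_motifs.parse(handle, "jaspar"))
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        colsums = counts.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValueError(
                f"PFM {m.matrix_id or m.name}: column sums to zero")
        probs = counts / colsums
        out.append(PWM(m.matrix_id or "", m.name or "", probs))
    return out


def read_jaspar_pfm(source) -> PWM:
    """Parse a single JASPAR PFM record."""
    pwms = read_jaspar_pfms(source)
    if len(pwms) != 1:
        raise ValueError(f"expected one PFM record, found {len(pwms)}")
    return pwms[0]


def write_jaspar_pfm(pwm_counts: Mapping[str, Sequence[float]], matrix_id,
                     name, path_or_handle) -> None:
    """Write one count matrix in JASPAR format."""
    lines = [f">{matrix_id} {name}"]
    for b in "ACGT":
        vals = " ".join(f"{v:.0f}" for v in pwm_counts[b])
        lines.append(f"{b} [ {vals} ]")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_handle, "write"):
        path_or_handle.write(text)
    else:
        with open(path_or_handle, "a") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# TSV tables


def read_count_matrix(path) -> pd.DataFrame:
    """Gene x sample integer count table (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative values")
    return df.astype(np.int64)


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


METADATA_COLUMNS = ["sample_id", "species", "cross", "stage", "role",
                    "maternal_population", "paternal_population"]


def read_sample_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return df


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


ALLELE_COUNT_COLUMNS = ["sample_id", "gene_id", "scaffold", "position",
                        "maternal_count", "paternal_count"]


def read_allele_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ALLELE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table missing columns: {sorted(missing)}")
    if (df[["maternal_count", "paternal_count"]].values < 0).any():
        raise ValueError("allele counts must be nonnegative")
    return df


def write_allele_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
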