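import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from cistrans.config import FilterConfig, SimConfig
from cistrans import formats_io as fio
from cistrans.formats_io import HOM_REF, HET, HOM_ALT, MISSING


VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=scaf1>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    """)


def write_vcf(tmp_path, body, samples):
    path = tmp_path / "toy.vcf"
    header = (VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
              "\tFORMAT\t" + "\t".join(samples) + "\n")
    path.write_text(header + textwrap.dedent(body))
    return path


class TestGenotypeMatrixFilters:
    def test_low_maf_site_dropped(self, tmp_path):
        # 13 samples, site 2 has a single alt allele: freq 1/26 ~ 0.038 < 0.05
        samples = [f"s{i}" for i in range(1, 14)]
        gts_common = "\t".join(["0/1:99"] * 13)
        gts_rare = "\t".join(["0/1:99"] + ["0/0:99"] * 12)
        body = (f"scaf1\t100\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t{gts_common}\n"
                f"scaf1\t200\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t{gts_rare}\n"
                f"scaf1\t300\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t{gts_common}\n")
        path = write_vcf(tmp_path, body, samples)
        gm = fio.read_genotype_matrix(path, {s: "A" for s in samples})
        assert gm.n_sites == 2
        assert list(gm.sites["position"]) == [100, 300]

    def test_missing_genotype_passthrough_and_call_rate(self, tmp_path):
        samples = [f"s{i}" for i in range(1, 11)]
        # site 1: one ./. among 10 (rate 0.9, kept, stored missing)
        gts1 = "\t".join(["./.:99"] + ["0/1:99"] * 9)
        # site 2: only 4 of 10 called -> rate 0.4 <= 0.5, dropped
        gts2 = "\t".join(["0/1:99"] * 4 + ["./.:99"] * 6)
        body = (f"scaf1\t100\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t{gts1}\n"
                f"scaf1\t200\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t{gts2}\n")
        path = write_vcf(tmp_path, body, samples)
        gm = fio.read_genotype_matrix(path, {s: "A" for s in samples})
        assert gm.n_sites == 1
        assert gm.genotypes[0, 0] == MISSING
        assert (gm.genotypes[0, 1:] == HET).all()

    def test_low_gq_masked_to_missing(self, tmp_path):
        samples = [f"s{i}" for i in range(1, 5)]
        gts = "0/1:10\t0/1:99\t1/1:99\t0/0:99"
        body = f"scaf1\t100\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t{gts}\n"
        path = write_vcf(tmp_path, body, samples)
        gm = fio.read_genotype_matrix(path, {s: "A" for s in samples})
        assert gm.n_sites == 1
        assert gm.genotypes[0, 0] == MISSING  # GQ 10 < 20 masked
        assert gm.genotypes[0, 2] == HOM_ALT

    def test_unlabeled_sample_fails(self, tmp_path):
        samples = ["s1", "s2"]
        body = "scaf1\t100\t.\tA\tG\t.\tPASS\t.\tGT:GQ\t0/1:99\t0/1:99\n"
        path = write_vcf(tmp_path, body, samples)
        with pytest.raises(ValueError, match="population label"):
            fio.read_genotype_matrix(path, {"s1": "A"})

    @pytest.mark.parametrize("knob", ["min_maf", "min_call_rate"])
    def test_filter_monotonicity(self, tmp_path, knob):
        """Raising a site filter never increases the retained site count."""
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(1, 13)]
        lines = []
        for k in range(30):
            cells = []
            for _ in samples:
                if rng.random() < 0.25:
                    cells.append("./.:99")
                else:
                    g = rng.choice(["0/0", "0/1", "1/1"],
                                   p=[0.5, 0.3, 0.2])
                    cells.append(f"{g}:99")
            lines.append(f"scaf1\t{100 + k * 50}\t.\tA\tG\t.\tPASS\t.\t"
                         "GT:GQ\t" + "\t".join(cells))
        path = write_vcf(tmp_path, "\n".join(lines) + "\n", samples)
        labels = {s: "A" for s in samples}
        counts = []
        for value in (0.0, 0.2, 0.4, 0.6, 0.8):
            f = FilterConfig(**{knob: value})
            counts.append(fio.read_genotype_matrix(path, labels, f).n_sites)
        assert counts == sorted(counts, reverse=True)

    def test_vcf_round_trip(self, tmp_path):
        """Write -> read reproduces genotypes, positions and alleles exactly."""
        from cistrans.synthetic_data import simulate_dataset

        ds = simulate_dataset(SimConfig(
            n_genes=20, n_fixed_snps=8, n_differentiated_snps=10,
            n_background_snps=15, n_fixed_deletions=2, n_background_svs=5,
            n_crosses=1, stages=("2dpf",), seed=9))
        path = tmp_path / "rt.vcf"
        fio.write_genotype_matrix_vcf(ds.genotypes, path)
        back = fio.read_genotype_matrix(path, ds.genotypes.populations)
        assert back.n_sites == ds.genotypes.n_sites
        pd.testing.assert_frame_equal(
            back.sites.reset_index(drop=True),
            ds.genotypes.sites.reset_index(drop=True))
        assert (back.genotypes == ds.genotypes.genotypes).all()


class TestSVCallSetIO:
    def test_sv_round_trip(self, tmp_path, tiny_dataset):
        cs = tiny_dataset.sv_call_sets[0]
        path = tmp_path / "sv.vcf"
        fio.write_sv_call_set_vcf(cs, path)
        back = fio.read_sv_call_set(path, cs.source_id)
        pd.testing.assert_frame_equal(back.records, cs.records)
        assert (back.genotypes == cs.genotypes).all()

    def test_missing_svtype_fails(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(VCF_HEADER +
                        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
                        "\tFORMAT\ts1\n"
                        "scaf1\t100\t.\tN\t<DEL>\t.\tPASS\t.\tGT\t1/1\n")
        with pytest.raises(ValueError, match="SVTYPE"):
            fio.read_sv_call_set(path)


class TestGeneModels:
    GFF = textwrap.dedent("""\
        ##gff-version 3
        scaf1\t.\tgene\t1000\t5000\t.\t+\t.\tID=geneA
        scaf1\t.\texon\t3000\t3500\t.\t+\t.\tID=geneA.e2;Parent=geneA
        scaf1\t.\texon\t1000\t1200\t.\t+\t.\tID=geneA.e1;Parent=geneA
        scaf1\t.\texon\t4800\t5000\t.\t+\t.\tID=geneA.e3;Parent=geneA
        scaf2\t.\tgene\t200\t900\t.\t-\t.\tID=geneB
        scaf2\t.\texon\t700\t900\t.\t-\t.\tID=geneB.e1;Parent=geneB
        scaf2\t.\texon\t200\t400\t.\t-\t.\tID=geneB.e2;Parent=geneB
        """)

    def test_exons_sorted_and_spans(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(self.GFF)
        models = {g.gene_id: g for g in fio.read_gene_models(path)}
        assert set(models) == {"geneA", "geneB"}
        a = models["geneA"]
        assert a.exons == [(1000, 1200), (3000, 3500), (4800, 5000)]
        assert a.span == (1000, 5000)
        # minus-strand span still in ascending genomic coordinates
        b = models["geneB"]
        assert b.strand == "-"
        assert b.span == (200, 900)

    def test_overlapping_exons_merged(self):
        gm = fio.GeneModel("g", "s", "+", [(100, 250), (200, 300), (400, 500)])
        assert gm.exons == [(100, 300), (400, 500)]

    def test_gff3_round_trip(self, tmp_path, tiny_dataset):
        path = tmp_path / "genes.gff3"
        fio.write_gene_models_gff3(tiny_dataset.gene_models, path)
        back = fio.read_gene_models(path)
        assert len(back) == len(tiny_dataset.gene_models)
        for orig, rt in zip(tiny_dataset.gene_models,
                            sorted(back, key=lambda g: g.gene_id)):
            assert rt.exons == orig.exons
            assert rt.span == orig.span


class TestJaspar:
    def test_counts_normalized(self):
        text = (">MA0001.1 toy\n"
                "A [ 10 1 0 ]\n"
                "C [ 0 1 5 ]\n"
                "G [ 0 1 5 ]\n"
                "T [ 0 1 0 ]\n")
        pwm = fio.read_jaspar_pfm(io.StringIO(text))
        assert pwm.matrix_id == "MA0001.1"
        np.testing.assert_allclose(pwm.probabilities[:, 0], [1, 0, 0, 0])
        np.testing.assert_allclose(pwm.probabilities[:, 1], [0.25] * 4)
        np.testing.assert_allclose(pwm.probabilities[:, 2], [0, .5, .5, 0])

    def test_matrix_id_retained(self):
        text = (">MA0056.1 MZF1\n"
                "A [ 1 2 3 ]\nC [ 1 0 0 ]\nG [ 1 0 1 ]\nT [ 1 2 0 ]\n")
        pwm = fio.read_jaspar_pfm(io.StringIO(text))
        assert pwm.matrix_id == "MA0056.1"
        assert pwm.name == "MZF1"

    def test_zero_column_fails(self):
        text = ">M1 t\nA [ 0 1 ]\nC [ 0 1 ]\nG [ 0 1 ]\nT [ 0 1 ]\n"
        with pytest.raises(ValueError, match="zero"):
            fio.read_jaspar_pfm(io.StringIO(text))
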