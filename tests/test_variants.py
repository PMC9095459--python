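"""Variant reading, functional classification, and the MAF filter."""

import numpy as np
import pytest

from binburden.variants import (
    FunctionalCategory as FC,
    Gene,
    GeneModel,
    VariantRecord,
    classify_variant,
    filter_common,
    is_common,
    read_af_table,
    read_genotypes,
)

from conftest import make_toy_gene_model


def var(pos, ref, alt, chrom="chr1", category=None):
    return VariantRecord(chrom, pos, ref, alt, category=category)


class TestClassify:
    """Toy gene: CDS codons ATG GCT CGA TAT GGT AAA CCC GGG TTT over
    [1011,1030]+[1041,1047]; 5'UTR [1001,1010]; intron [1031,1040];
    3'UTR [1048,1060]; ncRNA gene [2001,2500]."""

    @pytest.mark.parametrize(
        "variant, expected",
        [
            (var(1017, "C", "T"), FC.STOPCODON),  # CGA -> TGA
            (var(1014, "G", "C"), FC.NONSYNONYMOUS),  # GCT -> CCT (Ala->Pro)
            (var(1042, "G", "A"), FC.NONSYNONYMOUS),  # GGG -> AGG, codon after the intron
            (var(1014, "G", "GA"), FC.FRAMESHIFT),  # +1 insertion in CDS
            (var(1014, "GCT", "G"), FC.FRAMESHIFT),  # -2 deletion in CDS
            (var(1014, "G", "GAAA"), FC.NONSYNONYMOUS),  # in-frame insertion
            (var(1005, "A", "G"), FC.UTR),  # 5' UTR
            (var(1050, "A", "G"), FC.UTR),  # 3' UTR
            (var(1035, "A", "G"), FC.INTRONIC),
            (var(2100, "A", "G"), FC.NCRNA),
            (var(5000, "A", "G"), FC.INTERGENIC),  # overlaps nothing
        ],
    )
    def test_categories(self, toy_gene_model, variant, expected):
        assert classify_variant(variant, toy_gene_model) is expected

    def test_synonymous_has_no_category(self, toy_gene_model):
        # TTT -> TTC, both Phe
        assert classify_variant(var(1047, "T", "C"), toy_gene_model) is None

    def test_precomputed_category_passes_through(self, toy_gene_model):
        v = var(5000, "A", "G", category=FC.UTR)
        assert classify_variant(v, toy_gene_model) is FC.UTR

    def test_ref_mismatch_against_cds_is_error(self, toy_gene_model):
        with pytest.raises(ValueError, match="does not match ref"):
            classify_variant(var(1017, "A", "T"), toy_gene_model)

    def test_ncrna_outranks_intronic_of_overlapping_gene(self, toy_gene_model):
        nc_in_intron = Gene("NCI", "chr1", "+", 1031, 1040, exons=[(1031, 1040)], coding=False)
        model = GeneModel(toy_gene_model.genes + [nc_in_intron])
        assert classify_variant(var(1035, "A", "G"), model) is FC.NCRNA

    def test_coding_effect_outranks_everything(self, toy_gene_model):
        nc_over_cds = Gene("NCO", "chr1", "+", 1011, 1030, exons=[(1011, 1030)], coding=False)
        model = GeneModel(toy_gene_model.genes + [nc_over_cds])
        assert classify_variant(var(1017, "C", "T"), model) is FC.STOPCODON

    def test_minus_strand_codon_logic(self):
        # Same CDS codons as the toy gene but transcribed right-to-left:
        # spliced offset of genomic pos p is 127 - p; alleles complement.
        gene = Gene(
            "NEG", "chr1", "-", 101, 127,
            exons=[(101, 127)], cds=[(101, 127)], coding=True,
            cds_seq="ATGGCTCGATATGGTAAACCCGGGTTT",
        )
        model = GeneModel([gene])
        # offset 0 ('A' of ATG): genomic ref T; T>C makes ATG->GTG (Met->Val)
        assert classify_variant(var(127, "T", "C"), model) is FC.NONSYNONYMOUS
        # offset 6 ('C' of CGA): genomic ref G; G>A makes CGA->TGA (stop)
        assert classify_variant(var(121, "G", "A"), model) is FC.STOPCODON

    def test_no_gene_model_and_no_category_rejected(self):
        with pytest.raises(ValueError, match="no gene model"):
            classify_variant(var(5, "A", "G"), None)

    def test_agrees_with_interval_membership_oracle(self, rng):
        """Non-coding classification equals a brute-force oracle that
        checks interval membership with explicit precedence."""
        model = make_toy_gene_model()
        for _ in range(300):
            pos = int(rng.integers(900, 3000))
            v = var(pos, "A", "G")
            coding_gene, nc_gene = model.genes
            if coding_gene.in_cds(pos):
                continue  # codon-level effects are checked above
            if coding_gene.in_exon(pos):
                expected = FC.UTR
            elif nc_gene.contains(pos):
                expected = FC.NCRNA
            elif coding_gene.contains(pos):
                expected = FC.INTRONIC
            else:
                expected = FC.INTERGENIC
            assert classify_variant(v, model) is expected


class TestVariantRecord:
    def test_rejects_ref_equal_alt(self):
        with pytest.raises(ValueError, match="ref == alt"):
            var(10, "A", "A")

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValueError, match="position"):
            var(0, "A", "G")


class TestMafFilter:
    def test_af_above_threshold_removed(self):
        table = {("chr1", 10, "A", "G"): 0.06}
        assert filter_common([var(10, "A", "G")], table, 0.05) == []

    def test_af_exactly_threshold_retained(self):
        table = {("chr1", 10, "A", "G"): 0.05}
        assert len(filter_common([var(10, "A", "G")], table, 0.05)) == 1

    def test_absent_from_table_retained(self):
        assert len(filter_common([var(10, "A", "G")], {}, 0.05)) == 1

    def test_minor_allele_folding(self):
        # AF 0.97 folds to minor 0.03 (kept); AF 0.9 folds to 0.1 (removed)
        table = {("chr1", 10, "A", "G"): 0.97, ("chr1", 20, "A", "G"): 0.9}
        kept = filter_common([var(10, "A", "G"), var(20, "A", "G")], table, 0.05)
        assert [v.pos for v in kept] == [10]
        assert kept[0].population_af == 0.97

    def test_idempotent(self):
        table = {("chr1", 10, "A", "G"): 0.2}
        variants = [var(10, "A", "G"), var(20, "A", "G"), var(30, "C", "T")]
        once = filter_common(variants, table, 0.05)
        assert filter_common(once, table, 0.05) == once

    def test_rejects_bad_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_common([], {}, 0.0)

    def test_af_table_rejects_out_of_range(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\nchr1\t10\tA\tG\t1.2\n")
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            read_af_table(path)

    def test_af_table_round_trip(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text("chrom\tpos\tref\talt\taf\n1\t10\tA\tG\t0.25\n")
        table = read_af_table(path)
        assert table[("chr1", 10, "A", "G")] == 0.25
        assert is_common(var(10, "A", "G"), table, 0.05)


class TestReadGenotypes:
    def test_parse_counts_and_presence(self, toy_vcf):
        samples, stream = read_genotypes(toy_vcf)
        records = list(stream)
        assert samples == ["S1", "S2", "S3"]
        # 5 VCF rows, one multiallelic -> 6 decomposed records
        assert len(records) == 6
        assert sum(r[1].shape[0] for r in records) == 18
        rec, carries, dosage = records[0]
        assert (rec.chrom, rec.pos, rec.ref, rec.alt) == ("chr1", 100, "A", "G")
        assert carries.tolist() == [True, False, True]
        assert dosage.tolist() == [1, 0, 2]

    def test_missing_genotype_is_noncarrier(self, toy_vcf):
        _, stream = read_genotypes(toy_vcf)
        rec, carries, _ = list(stream)[1]
        assert rec.pos == 200
        assert carries.tolist() == [False, True, False]

    def test_multiallelic_decomposition(self, toy_vcf):
        _, stream = read_genotypes(toy_vcf)
        at_400 = [(r.alt, c.tolist(), d.tolist()) for r, c, d in stream if r.pos == 400]
        assert at_400 == [
            ("C", [True, True, False], [1, 1, 0]),
            ("T", [True, False, True], [1, 0, 1]),
        ]

    def test_sample_subset(self, toy_vcf):
        samples, stream = read_genotypes(toy_vcf, ["S3", "S1"])
        rec, carries, dosage = next(iter(stream))
        assert set(samples) == {"S1", "S3"}
        assert len(carries) == 2

    def test_unknown_sample_rejected(self, toy_vcf):
        with pytest.raises(ValueError, match="not in VCF header"):
            read_genotypes(toy_vcf, ["S1", "S9"])


def test_gff3_round_trip(tmp_path, toy_gene_model):
    path = tmp_path / "genes.gff3"
    toy_gene_model.to_gff3(path)
    back = GeneModel.from_gff3(path)
    assert len(back.genes) == len(toy_gene_model.genes)
    for a, b in zip(
        sorted(toy_gene_model.genes, key=lambda g: g.name),
        sorted(back.genes, key=lambda g: g.name),
    ):
        assert (a.name, a.chrom, a.strand, a.start, a.end) == (b.name, b.chrom, b.strand, b.start, b.end)
        assert a.exons == b.exons and a.cds == b.cds
        assert a.coding == b.coding and a.cds_seq == b.cds_seq
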