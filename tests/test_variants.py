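import dataclasses

import pandas as pd
import pytest

from crossnovex.genome import AnnotatedGenome, GeneModel, revcomp
from crossnovex.variants import (
    CodingContext,
    VariantRecord,
    call_consequence,
    call_consequence_cds,
    classify_region,
    filter_variants,
    intersect_with_de,
)


def variant(pos, ref="A", alt="G", chrom="chr1", **kwargs):
    defaults = dict(dp=20, gq=40, qual=500.0)
    defaults.update(kwargs)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, **defaults)


class TestFilterVariants:
    @pytest.mark.parametrize(
        ("quals", "kept"),
        [
            (dict(dp=5, gq=30, qual=165.0), False),  # '>5' strict
            (dict(dp=13, gq=30, qual=165.0), True),
            (dict(dp=100, gq=21, qual=80.0), False),  # qual not > 80
            (dict(dp=6, gq=20, qual=500.0), False),  # gq not > 20
            (dict(dp=6, gq=21, qual=81.0), True),
        ],
    )
    def test_strict_thresholds(self, quals, kept):
        got = filter_variants([variant(100, **quals)])
        assert bool(got) is kept


@pytest.fixture()
def toy_genes():
    # plus-strand coding gene: exons [100,220]+[321,440], CDS interior,
    # UTRs at the transcript ends
    gene = GeneModel(
        "gA", "chr1", "+",
        exons=[(100, 220), (321, 440)],
        cds=[(160, 220), (321, 380)],
        utr5=[(100, 159)],
        utr3=[(381, 440)],
    )
    far = GeneModel(
        "gB", "chr1", "+", exons=[(8000, 8500)], cds=[(8100, 8400)],
        utr5=[(8000, 8099)], utr3=[(8401, 8500)],
    )
    return [gene, far]


class TestClassifyRegion:
    def test_mid_cds_is_coding(self, toy_genes):
        assert classify_region(variant(200), toy_genes) == "coding"

    @pytest.mark.parametrize("pos", [221, 222, 319, 320])
    def test_first_two_intron_bases_are_splicing(self, toy_genes, pos):
        assert classify_region(variant(pos), toy_genes) == "splicing"

    def test_deep_intron_is_intronic(self, toy_genes):
        assert classify_region(variant(270), toy_genes) == "intronic"

    def test_utrs(self, toy_genes):
        assert classify_region(variant(120), toy_genes) == "UTR5"
        assert classify_region(variant(400), toy_genes) == "UTR3"

    def test_strand_aware_flanks(self, toy_genes):
        assert classify_region(variant(50), toy_genes) == "upstream"
        assert classify_region(variant(600), toy_genes) == "downstream"
        minus = [dataclasses.replace(g, strand="-") for g in toy_genes]
        assert classify_region(variant(50), minus) == "downstream"
        assert classify_region(variant(600), minus) == "upstream"

    def test_between_two_flanked_genes_is_combined(self):
        left = GeneModel("L", "chr1", "+", exons=[(100, 500)])
        right = GeneModel("R", "chr1", "+", exons=[(1200, 1600)])
        assert (
            classify_region(variant(850), [left, right])
            == "downstream+upstream"
        )

    def test_intergenic_when_no_gene_within_flank(self, toy_genes):
        assert classify_region(variant(5000), toy_genes) == "intergenic"

    def test_unknown_chromosome_rejected(self, toy_genes):
        with pytest.raises(KeyError):
            classify_region(variant(5, chrom="chrZ"), toy_genes,
                            known_chroms=["chr1"])

    def test_coding_outranks_flank_of_neighbor(self, toy_genes):
        near = GeneModel("N", "chr1", "+", exons=[(500, 900)])
        assert classify_region(variant(200), toy_genes + [near]) == "coding"


class TestCallConsequenceCds:
    def test_synonymous_third_base_wobble(self):
        cds = "ATG" + "GGA" + "TAA"
        cons = call_consequence_cds(cds, "GCTGCT", 6, "G")
        assert cons.effect == "synonymous"
        assert cons.hgvs_p == "p.Gly2="

    def test_missense(self):
        cds = "ATG" + "AAA" + "TAA"
        cons = call_consequence_cds(cds, "GCTGCT", 4, "C")
        assert cons.effect == "nonsynonymous"
        assert cons.hgvs_p == "p.Lys2Gln"

    def test_stopgain_formats_star(self):
        cds = "ATG" + "CAA" + "GCT" + "TAA"
        cons = call_consequence_cds(cds, "GCT", 4, "T")
        assert cons.effect == "stopgain"
        assert cons.hgvs_c == "c.4C>T"
        assert cons.hgvs_p == "p.Gln2*"

    def test_stoploss_counts_extension_to_first_utr_stop(self):
        cds = "ATG" + "GCT" + "TAA"
        utr3 = "GCT" * 4 + "TGA" + "ACGT"
        cons = call_consequence_cds(cds, utr3, 7, "C")  # TAA -> CAA (Gln)
        assert cons.effect == "stoploss"
        assert cons.ext_length == 5
        assert cons.hgvs_p == "p.*3Glnext*5"

    def test_stoploss_without_downstream_stop_is_unknown(self):
        cds = "ATG" + "GCT" + "TAA"
        cons = call_consequence_cds(cds, "GCT" * 6, 7, "C")
        assert cons.ext_length == "?"
        assert cons.hgvs_p == "p.*3Glnext*?"

    def test_stop_to_stop_is_synonymous(self):
        cds = "ATG" + "GCT" + "TAA"
        cons = call_consequence_cds(cds, "GCTGCT", 9, "G")  # TAA -> TAG
        assert cons.effect == "synonymous"

    def test_position_outside_cds_rejected(self):
        with pytest.raises(ValueError):
            call_consequence_cds("ATGTAA", "GCT", 9, "C")


class TestGenomicConsequences:
    def build_genome(self, strand):
        # single-exon gene, CDS = ATG CAA GCT TAA, 3' UTR with stop at codon 2
        cds = "ATG" + "CAA" + "GCT" + "TAA"
        utr5, utr3 = "GGGG", "GCT" + "TAA" + "CC"
        transcript = utr5 + cds + utr3
        start = 11
        if strand == "+":
            seq = "A" * 10 + transcript + "A" * 10
        else:
            seq = "A" * 10 + revcomp(transcript) + "A" * 10
        end = start + len(transcript) - 1
        if strand == "+":
            cds_iv = [(start + 4, start + 15)]
            utr5_iv = [(start, start + 3)]
            utr3_iv = [(start + 16, end)]
        else:
            cds_iv = [(end - 15, end - 4)]
            utr5_iv = [(end - 3, end)]
            utr3_iv = [(start, start + 7)]
        gene = GeneModel("g", "chr1", strand, exons=[(start, end)],
                         cds=cds_iv, utr5=utr5_iv, utr3=utr3_iv)
        return AnnotatedGenome({"chr1": seq}, [gene]), gene

    def test_plus_strand_stopgain(self):
        genome, gene = self.build_genome("+")
        # c.4 C>T makes CAA -> TAA
        pos = gene.cds[0][0] + 3
        cons = call_consequence(variant(pos, ref="C", alt="T"), gene, genome)
        assert cons.effect == "stopgain"
        assert cons.hgvs_p == "p.Gln2*"

    def test_minus_strand_alleles_are_complemented(self):
        genome, gene = self.build_genome("-")
        context = CodingContext.from_gene(gene, genome)
        assert context.cds_seq == "ATGCAAGCTTAA"
        # genomic G>A on the minus strand is coding C>T
        pos = context._cds_positions[3]
        cons = call_consequence(variant(pos, ref="G", alt="A"), gene, genome)
        assert cons.effect == "stopgain"
        assert cons.hgvs_c == "c.4C>T"

    def test_strand_symmetry_of_consequences(self):
        plus, gene_p = self.build_genome("+")
        minus, gene_m = self.build_genome("-")
        # same coding change delivered from either strand orientation
        pos_p = gene_p.cds[0][0] + 3
        ctx = CodingContext.from_gene(gene_m, minus)
        pos_m = ctx._cds_positions[3]
        cons_p = call_consequence(variant(pos_p, ref="C", alt="T"), gene_p, plus)
        cons_m = call_consequence(variant(pos_m, ref="G", alt="A"), gene_m, minus)
        assert (cons_p.effect, cons_p.hgvs_c, cons_p.hgvs_p) == (
            cons_m.effect, cons_m.hgvs_c, cons_m.hgvs_p,
        )

    def test_variant_outside_cds_directed_to_classifier(self):
        genome, gene = self.build_genome("+")
        with pytest.raises(ValueError, match="classify_region"):
            call_consequence(variant(gene.utr3[0][0]), gene, genome)

    def test_reference_mismatch_warns(self):
        genome, gene = self.build_genome("+")
        pos = gene.cds[0][0] + 3  # reference base is C
        with pytest.warns(UserWarning, match="disagrees"):
            call_consequence(variant(pos, ref="T", alt="G"), gene, genome)


class TestIntersectWithDe:
    def consequence(self, gene_id, effect="nonsynonymous"):
        from crossnovex.variants import Consequence

        return Consequence(effect=effect, hgvs_c="c.1A>G", hgvs_p="p.X",
                           codon=1, gene_id=gene_id)

    def de_frame(self, rows):
        return pd.DataFrame(rows).set_index("gene")

    def test_empty_de_set_gives_empty_table(self):
        de = self.de_frame(
            [{"gene": "g1", "log2fc": 3.0, "fdr": 0.5, "is_de": False}]
        )
        out = intersect_with_de([(variant(1), self.consequence("g1"))], de)
        assert out.empty

    def test_single_join_labels_direction(self):
        de = self.de_frame(
            [{"gene": "g1", "log2fc": 3.0, "fdr": 0.001, "is_de": True}]
        )
        out = intersect_with_de([(variant(1), self.consequence("g1"))], de)
        assert len(out) == 1
        assert out.iloc[0]["group"] == "up_in_a"

    def test_synonymous_variants_excluded(self):
        de = self.de_frame(
            [{"gene": "g1", "log2fc": -3.0, "fdr": 0.001, "is_de": True}]
        )
        annotated = [
            (variant(1), self.consequence("g1", "synonymous")),
            (variant(2, ref="C", alt="T"), self.consequence("g1")),
        ]
        out = intersect_with_de(annotated, de)
        assert len(out) == 1
        assert out.iloc[0]["group"] == "up_in_b"
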