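"""Variant annotation: location precedence, coding effects, strand symmetry."""

import numpy as np
import pytest
from Bio.Seq import Seq

from apiscout import annotate
from apiscout.annotate import (
    GeneModel, Transcript, Variant, classify_effect, classify_location,
    nearby_gene_report,
)

# toy gene layout (see conftest TOY_GFF):
#   geneF (+): 10000-12999, exons 10000-10999 / 12000-12999,
#              CDS 10200-10999 / 12000-12399 -> 5'UTR 10000-10199, 3'UTR 12400-12999
#   geneR (-): 20000-22999, exons 20000-20999 / 22000-22999,
#              CDS 20500-20999 / 22000-22599 -> 5'UTR 22600-22999, 3'UTR 20000-20499
#   geneNC (+, ncRNA): 30000-30999, exons 30000-30399 / 30600-30999


class TestClassifyLocation:
    @pytest.mark.parametrize("pos,expected,gene", [
        (10500, "coding", "geneF"),
        (10154, "5'UTR", "geneF"),      # 46 bp upstream of the initiation codon
        (12441, "3'UTR", "geneF"),      # 42 bp after the stop codon, inside mRNA
        (11500, "intron", "geneF"),
        (30100, "coding", "geneNC"),    # ncRNA exon counts as coding
        (30500, "intron", "geneNC"),
        (22700, "5'UTR", "geneR"),      # reverse strand: 5'UTR at high coords
        (20100, "3'UTR", "geneR"),
        (9000, "upstream", "geneF"),    # 1000 bp before a + gene
        (13500, "downstream", "geneF"),
        (23500, "upstream", "geneR"),   # past the end of a - gene
        (19500, "downstream", "geneR"),
        (38000, "intergenic", None),    # > 5000 bp from everything
    ])
    def test_classes(self, toy_genes, pos, expected, gene):
        cls, gene_id, _ = classify_location(Variant("chrA", pos), toy_genes)
        assert cls == expected
        if gene is not None:
            assert gene_id == gene

    def test_flank_boundary(self, toy_genes):
        cls, _, dist = classify_location(Variant("chrA", 5000), toy_genes)
        assert cls == "upstream" and dist == 5000
        cls, _, dist = classify_location(Variant("chrA", 4999), toy_genes)
        assert cls == "intergenic"

    def test_missing_chromosome_is_intergenic(self, toy_genes):
        cls, gene_id, _ = classify_location(Variant("chrZ", 100), toy_genes)
        assert cls == "intergenic" and gene_id is None

    def test_tie_prefers_upstream(self):
        genes = [
            GeneModel("gL", "c", "+", 1000, 2000,
                      [Transcript("tL", "+", exons=[(1000, 2000)], cds=[(1000, 2000)])]),
            GeneModel("gR", "c", "+", 3000, 4000,
                      [Transcript("tR", "+", exons=[(3000, 4000)], cds=[(3000, 4000)])]),
        ]
        # position 2500: 500 bp downstream of gL and 500 bp upstream of gR
        cls, gene_id, dist = classify_location(Variant("c", 2500), genes)
        assert (cls, gene_id, dist) == ("upstream", "gR", 500)

    def test_agrees_with_bruteforce_interval_oracle(self):
        rng = np.random.default_rng(12)
        genes = []
        for i in range(50):
            start = int(rng.integers(1, 900_000))
            length = int(rng.integers(500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + length
            mid = start + length // 3
            genes.append(GeneModel(
                f"g{i}", "c", strand, start, end,
                [Transcript(f"t{i}", strand, exons=[(start, mid), (mid + 100, end)],
                            cds=[(start + 50, mid), (mid + 100, end - 50)])]))

        def oracle(pos):
            classes = []
            for g in genes:
                if g.start <= pos <= g.end:
                    tx = g.transcripts[0]
                    if any(a <= pos <= b for a, b in tx.cds):
                        classes.append("coding")
                    elif any(a <= pos <= b for a, b in tx.utr5):
                        classes.append("5'UTR")
                    elif any(a <= pos <= b for a, b in tx.utr3):
                        classes.append("3'UTR")
                    else:
                        classes.append("intron")
            if classes:
                for c in ("coding", "5'UTR", "3'UTR", "intron"):
                    if c in classes:
                        return c
            near = []
            for g in genes:
                d = g.start - pos if pos < g.start else pos - g.end
                if 0 < d <= 5000:
                    if pos < g.start:
                        side = "upstream" if g.strand == "+" else "downstream"
                    else:
                        side = "downstream" if g.strand == "+" else "upstream"
                    near.append((d, 0 if side == "upstream" else 1, side))
            if near:
                return min(near)[2]
            return "intergenic"

        for pos in rng.integers(1, 950_000, size=1000):
            got, _, _ = classify_location(Variant("c", int(pos)), genes)
            assert got == oracle(int(pos)), f"mismatch at {pos}"


class TestClassifyEffect:
    def make_gene(self, seq_len=60):
        rng = np.random.default_rng(8)
        chrom_seq = "".join(rng.choice(list("ACGT"), size=seq_len))
        tx = Transcript("t", "+", exons=[(11, 40)], cds=[(11, 40)])
        return chrom_seq, tx

    def test_all_snps_match_translation_oracle(self):
        chrom_seq, tx = self.make_gene()
        cds = chrom_seq[10:40]
        for pos in range(11, 41):
            ref = chrom_seq[pos - 1]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = classify_effect(Variant("c", pos, ref, alt, "SNP"), tx, chrom_seq)
                idx = pos - 11
                mutated = cds[:idx] + alt + cds[idx + 1:]
                same = str(Seq(cds).translate()) == str(Seq(mutated).translate())
                assert got == ("synonymous" if same else "codon-change")

    def test_reverse_strand_snp_uses_complement(self):
        # CDS 1-6 on '-' strand; genomic "ATGGCA" -> mRNA revcomp "TGCCAT"
        chrom_seq = "ATGGCA"
        tx = Transcript("t", "-", exons=[(1, 6)], cds=[(1, 6)])
        got = classify_effect(Variant("c", 6, "A", "G", "SNP"), tx, chrom_seq)
        # mRNA codon1 TGC (Cys) -> pos 6 is mRNA base 1: G>C complement -> CGC (Arg)
        assert got == "codon-change"

    @pytest.mark.parametrize("ref,alt,expected", [
        ("ATT", "A", "frameshift"),     # 2-nt deletion
        ("ATTT", "A", "inframe-indel"),  # 3-nt deletion
        ("A", "AT", "frameshift"),      # 1-nt insertion
    ])
    def test_indel_frame(self, ref, alt, expected):
        chrom_seq, tx = self.make_gene()
        assert classify_effect(Variant("c", 20, ref, alt, "indel"), tx, chrom_seq) \
            == expected

    def test_boundary_spanning_indel_is_other(self):
        chrom_seq, tx = self.make_gene()
        # deletion starting inside the CDS interval and running past its end
        v = Variant("c", 39, "ATTT", "A", "indel")
        assert classify_effect(v, tx, chrom_seq) == "other"

    def test_mirrored_genome_preserves_classes(self, toy_genes, toy_reference):
        """Reverse-complementing the genome and coordinates changes nothing."""
        length = len(toy_reference["chrA"])

        def mirror_iv(iv):
            return (length + 1 - iv[1], length + 1 - iv[0])

        mirrored = []
        for g in toy_genes:
            txs = []
            for t in g.transcripts:
                txs.append(Transcript(
                    t.transcript_id, "-" if t.strand == "+" else "+",
                    exons=sorted(mirror_iv(e) for e in t.exons),
                    cds=sorted(mirror_iv(c) for c in t.cds),
                    utr5=sorted(mirror_iv(u) for u in t.utr5),
                    utr3=sorted(mirror_iv(u) for u in t.utr3)))
            mirrored.append(GeneModel(
                g.gene_id, g.chrom, "-" if g.strand == "+" else "+",
                length + 1 - g.end, length + 1 - g.start, txs))
        rng = np.random.default_rng(13)
        for pos in rng.integers(1, length + 1, size=300):
            orig, _, d1 = classify_location(Variant("chrA", int(pos)), toy_genes)
            mirr, _, d2 = classify_location(
                Variant("chrA", length + 1 - int(pos)), mirrored)
            assert orig == mirr and d1 == d2


class TestNearbyGenes:
    def test_downstream_distance(self, toy_genes):
        report = nearby_gene_report(Variant("chrA", 13075), toy_genes)
        assert ("geneF", 76) in report  # 76 bp downstream of a + gene

    def test_inside_gene_distance_zero(self, toy_genes):
        assert ("geneF", 0) in nearby_gene_report(Variant("chrA", 11000), toy_genes)

    def test_empty_neighborhood(self, toy_genes):
        assert nearby_gene_report(Variant("chrA", 39990), toy_genes) == []

    def test_upstream_is_negative(self, toy_genes):
        report = nearby_gene_report(Variant("chrA", 9900), toy_genes)
        assert ("geneF", -100) in report


class TestGff3Reader:
    def test_utrs_derived_from_cds(self, toy_genes):
        gf = {g.gene_id: g for g in toy_genes}["geneF"]
        tx = gf.transcripts[0]
        assert tx.utr5 == [(10000, 10199)]
        assert tx.utr3 == [(12400, 12999)]
        gr = {g.gene_id: g for g in toy_genes}["geneR"]
        tx = gr.transcripts[0]
        assert tx.utr5 == [(22600, 22999)]
        assert tx.utr3 == [(20000, 20499)]

    def test_ncrna_has_no_cds(self, toy_genes):
        nc = {g.gene_id: g for g in toy_genes}["geneNC"]
        assert not nc.transcripts[0].is_coding
        assert len(nc.transcripts[0].exons) == 2

    def test_unsorted_features_accepted(self, tmp_path):
        text = (
            "##gff-version 3\n"
            "c\tx\tgene\t100\t400\t.\t+\t.\tID=g\n"
            "c\tx\tmRNA\t100\t400\t.\t+\t.\tID=t;Parent=g\n"
            "c\tx\texon\t300\t400\t.\t+\t.\tParent=t\n"
            "c\tx\texon\t100\t200\t.\t+\t.\tParent=t\n"
            "c\tx\tCDS\t300\t400\t.\t+\t.\tParent=t\n"
            "c\tx\tCDS\t150\t200\t.\t+\t.\tParent=t\n")
        path = tmp_path / "unsorted.gff3"
        path.write_text(text)
        genes = annotate.read_gff3(path)
        assert genes[0].transcripts[0].exons == [(100, 200), (300, 400)]
        assert genes[0].transcripts[0].cds == [(150, 200), (300, 400)]
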