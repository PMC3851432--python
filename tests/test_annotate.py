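"""Feature labelling, coding-effect calls and GO joins on toy gene models."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from dualmark.annotate import (
    attach_go,
    build_feature_index,
    classify_coding_snp,
)
from dualmark.polymorphism import PolymorphicMarker
from dualmark.simulate import GeneModel


def toy_gene(strand="+", chrom="chr1", gene_id="g1"):
    """A hand-built gene on a 300 bp chromosome.

    Plus strand transcript layout (genomic coordinates):
      UTR5 [50,60) | CDS1 [60,75) | intron [75,95) | CDS2 [95,110) | UTR3 [110,120)
    Minus strand mirrors the same intervals with roles swapped so the
    transcript still reads UTR5 -> CDS -> UTR3 on its own strand.
    """
    if strand == "+":
        return GeneModel(
            gene_id=gene_id, chrom=chrom, start=50, end=120, strand="+",
            exons=((50, 75), (95, 120)),
            cds=((60, 75), (95, 110)),
            utr5=((50, 60),), utr3=((110, 120),),
        )
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=50, end=120, strand="-",
        exons=((50, 75), (95, 120)),
        cds=((60, 75), (95, 110)),
        utr5=((110, 120),), utr3=((50, 60),),
    )


def toy_reference(cds_tx: str, strand="+"):
    """Chromosome whose CDS bases (transcript order) are ``cds_tx``."""
    rng = np.random.default_rng(8)
    seq = list("".join(rng.choice(list("ACGT"), size=300)))
    genome_cds = cds_tx if strand == "+" else str(Seq(cds_tx).reverse_complement())
    seq[60:75] = genome_cds[:15]
    seq[95:110] = genome_cds[15:]
    return {"chr1": "".join(seq)}


CDS30 = "ATG" + "GCT" * 8 + "TAA"  # Met, 8x Ala, stop — 30 bases


class TestFeatureIndex:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (65, "CDS"), (100, "CDS"),
            (55, "UTR5"), (115, "UTR3"),
            (80, "intron"),
            (10, "intergenic"), (200, "intergenic"),
        ],
    )
    def test_plus_strand_point_queries(self, pos, expected):
        index = build_feature_index([toy_gene("+")])
        feature, gene_id, _ = index.query("chr1", pos)
        assert feature == expected
        assert (gene_id == "g1") is (expected != "intergenic")

    def test_minus_strand_utr5_lies_downstream_in_genome_coordinates(self):
        index = build_feature_index([toy_gene("-")])
        assert index.query("chr1", 115)[0] == "UTR5"
        assert index.query("chr1", 55)[0] == "UTR3"

    def test_cds_not_multiple_of_three_flagged_and_refused(self):
        bad = GeneModel(
            gene_id="gbad", chrom="chr1", start=50, end=120, strand="+",
            exons=((50, 75), (95, 120)), cds=((60, 75), (95, 109)),
            utr5=((50, 60),), utr3=((110, 120),),
        )
        index = build_feature_index([bad])
        assert "gbad" in index.flagged
        ref = toy_reference(CDS30)
        with pytest.raises(ValueError, match="flagged"):
            classify_coding_snp("chr1", 65, ref["chr1"][65], "A", index, ref)

    def test_feature_lengths_partition_chromosome(self):
        index = build_feature_index([toy_gene("+")])
        counts = {"CDS": 0, "UTR5": 0, "UTR3": 0, "intron": 0, "intergenic": 0}
        for pos in range(300):
            counts[index.query("chr1", pos)[0]] += 1
        assert counts == {
            "CDS": 30, "UTR5": 10, "UTR3": 10, "intron": 20, "intergenic": 230,
        }


class TestCodingEffect:
    def test_third_position_ala_to_ala_is_synonymous(self):
        ref = toy_reference(CDS30)
        index = build_feature_index([toy_gene("+")])
        # codon 2 is GCT at transcript offsets 3..5 -> genomic 63..65
        assert ref["chr1"][65] == "T"
        assert classify_coding_snp("chr1", 65, "T", "C", index, ref) == "synonymous"

    def test_first_position_ala_to_pro_is_nonsynonymous(self):
        ref = toy_reference(CDS30)
        index = build_feature_index([toy_gene("+")])
        assert ref["chr1"][63] == "G"
        assert classify_coding_snp("chr1", 63, "G", "C", index, ref) == "nonsynonymous"

    def test_codon_spanning_splice_junction_uses_spliced_cds(self):
        ref = toy_reference(CDS30)
        index = build_feature_index([toy_gene("+")])
        # transcript offset 15 (first base of codon 6) is the first base of
        # the second CDS exon, genomic 95; GCT -> CCT is Ala -> Pro
        assert ref["chr1"][95] == "G"
        assert classify_coding_snp("chr1", 95, "G", "C", index, ref) == "nonsynonymous"

    def test_reference_mismatch_raises(self):
        ref = toy_reference(CDS30)
        index = build_feature_index([toy_gene("+")])
        wrong = "A" if ref["chr1"][65] != "A" else "C"
        with pytest.raises(ValueError, match="mismatch"):
            classify_coding_snp("chr1", 65, wrong, "G", index, ref)

    def test_strand_matters_for_the_same_genomic_substitution(self):
        # plus-strand CGA (Arg); C->T at codon position 1 gives TGA — on the
        # minus strand the same genomic substitution edits a different codon
        # position of the reverse-complement transcript
        cds_plus = "ATG" + "CGA" * 8 + "TAA"
        ref_p = toy_reference(cds_plus, "+")
        idx_p = build_feature_index([toy_gene("+")])
        pos = 63  # codon 2 position 1
        assert ref_p["chr1"][pos] == "C"
        eff_plus = classify_coding_snp("chr1", pos, "C", "T", idx_p, ref_p)
        assert eff_plus == "nonsynonymous"  # Arg -> stop

        ref_m = toy_reference(cds_plus, "-")
        idx_m = build_feature_index([toy_gene("-")])
        base = ref_m["chr1"][pos]
        eff_minus = classify_coding_snp(
            "chr1", pos, base, "T" if base != "T" else "C", idx_m, ref_m
        )
        assert eff_minus in ("synonymous", "nonsynonymous")

    def test_six_frame_brute_force_agrees_on_every_cds_position(self):
        """Oracle: recompute each effect by translating the whole mutated CDS."""
        for strand in ("+", "-"):
            ref = toy_reference(CDS30, strand)
            gene = toy_gene(strand)
            index = build_feature_index([gene])
            seq = ref["chr1"]
            for pos in [p for s, e in gene.cds for p in range(s, e)]:
                base = seq[pos]
                alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
                got = classify_coding_snp("chr1", pos, base, alt, index, ref)
                # brute force: splice, mutate, orient, translate both
                spliced = "".join(seq[s:e] for s, e in gene.cds)
                off = 0
                for s, e in gene.cds:
                    if s <= pos < e:
                        off += pos - s
                        break
                    off += e - s
                mut = spliced[:off] + alt + spliced[off + 1 :]
                if strand == "-":
                    spliced = str(Seq(spliced).reverse_complement())
                    mut = str(Seq(mut).reverse_complement())
                want = (
                    "synonymous"
                    if Seq(spliced).translate() == Seq(mut).translate()
                    else "nonsynonymous"
                )
                assert got == want, (strand, pos)

    def test_reverse_complementing_chromosome_preserves_effects(self):
        """Mirror the toy chromosome and its annotation; calls must agree."""
        ref = toy_reference(CDS30, "+")
        gene = toy_gene("+")
        index = build_feature_index([gene])
        n = len(ref["chr1"])
        flipped_seq = str(Seq(ref["chr1"]).reverse_complement())

        def flip(iv):
            return tuple(sorted((n - e, n - s) for s, e in iv))

        flipped_gene = GeneModel(
            gene_id="g1", chrom="chr1", start=n - gene.end, end=n - gene.start,
            strand="-", exons=flip(gene.exons), cds=flip(gene.cds),
            utr5=flip(gene.utr5), utr3=flip(gene.utr3),
        )
        flipped_ref = {"chr1": flipped_seq}
        flipped_index = build_feature_index([flipped_gene])
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for pos in [p for s, e in gene.cds for p in range(s, e)]:
            base = ref["chr1"][pos]
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
            fwd = classify_coding_snp("chr1", pos, base, alt, index, ref)
            mpos = n - 1 - pos
            rev = classify_coding_snp(
                "chr1", mpos, comp[base], comp[alt], flipped_index, flipped_ref
            )
            assert fwd == rev


def _marker(gene_id):
    m = PolymorphicMarker(marker_type="SNP", chrom="chr1", pos=0)
    m.gene_id = gene_id
    m.feature = "CDS"
    return m


class TestAttachGo:
    def test_annotated_fraction(self):
        markers = [_marker(f"g{i}") for i in range(10)]
        mapping = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "go_id": [f"GO:{i:07d}" for i in range(6)],
                "category": ["biological process"] * 6,
            }
        )
        out = attach_go(markers, mapping)
        assert out["annotated_percent"] == 60.0
        assert len(out["marker_genes"]) == 10 and len(out["annotated_genes"]) == 6

    def test_gene_counted_once_per_category_and_once_overall(self):
        markers = [_marker("g1")]
        mapping = pd.DataFrame(
            {
                "gene_id": ["g1", "g1"],
                "go_id": ["GO:0000001", "GO:0000002"],
                "category": ["biological process", "molecular function"],
            }
        )
        out = attach_go(markers, mapping)
        assert out["annotated_genes"] == {"g1"}
        assert out["category_counts"]["biological process"] == 1
        assert out["category_counts"]["molecular function"] == 1

    def test_unknown_category_skipped(self):
        markers = [_marker("g1")]
        mapping = pd.DataFrame(
            {"gene_id": ["g1"], "go_id": ["GO:1"], "category": ["bogus"]}
        )
        out = attach_go(markers, mapping)
        assert out["annotated_percent"] == 0.0

    def test_empty_mapping(self):
        out = attach_go(
            [_marker("g1")],
            pd.DataFrame(columns=["gene_id", "go_id", "category"]),
        )
        assert out["annotated_percent"] == 0.0
        assert all(v == 0 for v in out["category_counts"].values())
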