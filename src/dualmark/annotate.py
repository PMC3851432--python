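"""Genomic-feature annotation of markers and coding-effect calls.

Each marker position is assigned exactly one label — CDS, UTR5, UTR3,
intron or intergenic — with precedence CDS > UTR > intron > intergenic for
positions covered by overlapping features.  Coding SNPs are classified as
synonymous or nonsynonymous by rebuilding the affected codon from the
spliced CDS on the annotated strand and translating with the standard
nuclear genetic code.  GO terms are joined from a gene -> term mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .polymorphism import PolymorphicMarker
from .simulate import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureIndex",
    "build_feature_index",
    "annotate_markers",
    "classify_coding_snp",
    "attach_go",
    "GO_CATEGORIES",
]

GO_CATEGORIES = ("biological process", "cellular component", "molecular function")

_PRECEDENCE = {"CDS": 0, "UTR5": 1, "UTR3": 1, "intron": 2}


@dataclass
class FeatureIndex:
    """Interval index answering position -> (feature, gene, strand) queries."""

    trees: dict[str, IntervalTree]
    genes: dict[str, GeneModel]
    flagged: set[str]  # genes with CDS length not divisible by 3

    def query(self, chrom: str, pos: int) -> tuple[str, str | None, str | None]:
        """Label a 0-based position; returns (feature, gene_id, strand)."""
        tree = self.trees.get(chrom)
        if tree is None:
            return "intergenic", None, None
        hits = tree[pos]
        if not hits:
            return "intergenic", None, None
        best = min(
            hits,
            key=lambda iv: (_PRECEDENCE[iv.data[0]], iv.end - iv.begin, iv.data[1]),
        )
        feature, gene_id, strand = best.data
        return feature, gene_id, strand


def build_feature_index(genes: list[GeneModel]) -> FeatureIndex:
    """Index gene models for point queries.

    Intronic intervals are derived as gene span minus exons.  A gene whose
    CDS total length is not divisible by 3 is flagged; coding-effect calls
    for flagged genes are refused.
    """
    trees: dict[str, IntervalTree] = {}
    gene_map: dict[str, GeneModel] = {}
    flagged: set[str] = set()
    for g in genes:
        gene_map[g.gene_id] = g
        cds_total = sum(e - s for s, e in g.cds)
        if cds_total % 3 != 0:
            flagged.add(g.gene_id)
            logger.warning(
                "gene %s: CDS length %d not divisible by 3; coding-effect "
                "calls refused", g.gene_id, cds_total,
            )
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds:
            tree[s:e] = ("CDS", g.gene_id, g.strand)
        for s, e in g.utr5:
            tree[s:e] = ("UTR5", g.gene_id, g.strand)
        for s, e in g.utr3:
            tree[s:e] = ("UTR3", g.gene_id, g.strand)
        # introns: gene span minus exons
        exon_sorted = sorted(g.exons)
        for (s1, e1), (s2, e2) in zip(exon_sorted, exon_sorted[1:]):
            if e1 < s2:
                tree[e1:s2] = ("intron", g.gene_id, g.strand)
    return FeatureIndex(trees=trees, genes=gene_map, flagged=flagged)


def annotate_markers(
    markers: list[PolymorphicMarker],
    index: FeatureIndex,
    reference: dict[str, str] | None = None,
) -> list[PolymorphicMarker]:
    """Fill ``feature``/``gene_id`` for every marker in place (and return them).

    InDels and SSRs take the label of their leftmost (anchor) base only; a
    marker spanning a feature boundary keeps its anchor's label.  When a
    reference is supplied, coding SNPs additionally get a synonymous /
    nonsynonymous call.
    """
    for m in markers:
        feature, gene_id, _ = index.query(m.chrom, m.pos)
        m.feature = feature
        m.gene_id = gene_id
        if (
            m.marker_type == "SNP"
            and feature == "CDS"
            and reference is not None
            and gene_id not in index.flagged
            and not m.detail.get("multiallelic", False)
        ):
            alt = (
                m.detail["allele_a"]
                if m.detail["allele_a"] != m.detail["ref"]
                else m.detail["allele_b"]
            )
            m.coding_effect = classify_coding_snp(
                m.chrom, m.pos, m.detail["ref"], alt, index, reference
            )
    return markers


def classify_coding_snp(
    chrom: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    index: FeatureIndex,
    reference: dict[str, str],
) -> str:
    """Synonymous/nonsynonymous call for a SNP at a 0-based CDS position.

    The affected codon is assembled from the spliced CDS in transcript
    orientation; for minus-strand genes the genomic alternate allele is
    reverse-complemented.  Raises if the stated reference base disagrees
    with the reference sequence or the position is not in an (unflagged)
    CDS.
    """
    feature, gene_id, strand = index.query(chrom, pos)
    if feature != "CDS" or gene_id is None:
        raise ValueError(f"position {chrom}:{pos} is not in a CDS")
    if gene_id in index.flagged:
        raise ValueError(f"gene {gene_id} flagged (CDS not a multiple of 3)")
    seq = reference[chrom]
    if seq[pos].upper() != ref_base.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: sequence has {seq[pos]!r}, "
            f"call says {ref_base!r}"
        )
    gene = index.genes[gene_id]
    # spliced CDS in genomic order, and the SNP's offset within it
    cds_parts = sorted(gene.cds)
    spliced = "".join(seq[s:e] for s, e in cds_parts)
    offset = 0
    for s, e in cds_parts:
        if s <= pos < e:
            offset += pos - s
            break
        offset += e - s
    mutated = spliced[:offset] + alt_base.upper() + spliced[offset + 1 :]
    if gene.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
        offset = len(spliced) - 1 - offset
    codon_i = offset // 3
    codon_ref = spliced[codon_i * 3 : codon_i * 3 + 3]
    codon_alt = mutated[codon_i * 3 : codon_i * 3 + 3]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def attach_go(
    markers: list[PolymorphicMarker],
    go_mapping: pd.DataFrame,
) -> dict:
    """Join GO terms onto marker-containing genes and tally categories.

    ``go_mapping`` columns: ``gene_id``, ``go_id``, ``category`` (one of the
    three top-level ontologies).  Records with an unknown category are
    skipped with a warning.  Term counts tally term-gene pairs per category.

    Returns a dict with the marker-containing gene set, the annotated
    subset, the annotated fraction (percent, 1 d.p.) and per-category term
    counts.
    """
    marker_genes = {m.gene_id for m in markers if m.gene_id is not None}
    valid = go_mapping[go_mapping["category"].isin(GO_CATEGORIES)]
    dropped = len(go_mapping) - len(valid)
    if dropped:
        logger.warning("%d GO records with unknown category skipped", dropped)
    valid = valid[valid["gene_id"].isin(marker_genes)].drop_duplicates(
        subset=["gene_id", "go_id", "category"]
    )
    annotated = set(valid["gene_id"])
    category_counts = valid.groupby("category").size().to_dict()
    for cat in GO_CATEGORIES:
        category_counts.setdefault(cat, 0)
    frac = 100.0 * len(annotated) / len(marker_genes) if marker_genes else 0.0
    return {
        "marker_genes": marker_genes,
        "annotated_genes": annotated,
        "annotated_percent": round(frac, 1),
        "category_counts": category_counts,
    }
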