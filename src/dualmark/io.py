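"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open; GFF3 and all emitted tables are
1-based inclusive.  FASTA goes through Biopython; tables through pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import GenotypePanel, PanelCall
from .polymorphism import PolymorphicMarker
from .simulate import CallRecord, GeneModel
from .ssr import SSRLocus

CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "type", "length",
    "depth", "quality", "reads_ref", "reads_alt",
]


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene/mRNA/exon/CDS/UTR features, 1-based inclusive."""
    lines = ["##gff-version 3"]

    def row(chrom, ftype, s, e, strand, attrs, phase="."):
        return "\t".join(
            [chrom, "dualmark", ftype, str(s + 1), str(e), ".", strand, phase, attrs]
        )

    for g in genes:
        mrna_id = f"{g.gene_id}.t1"
        lines.append(row(g.chrom, "gene", g.start, g.end, g.strand, f"ID={g.gene_id}"))
        lines.append(
            row(g.chrom, "mRNA", g.start, g.end, g.strand,
                f"ID={mrna_id};Parent={g.gene_id}")
        )
        for i, (s, e) in enumerate(sorted(g.exons)):
            lines.append(
                row(g.chrom, "exon", s, e, g.strand,
                    f"ID={mrna_id}.exon{i + 1};Parent={mrna_id}")
            )
        # CDS phase: running remainder in translation order
        cds_tx = sorted(g.cds, reverse=(g.strand == "-"))
        done = 0
        phases = {}
        for s, e in cds_tx:
            phases[(s, e)] = (3 - done % 3) % 3
            done += e - s
        for s, e in sorted(g.cds):
            lines.append(
                row(g.chrom, "CDS", s, e, g.strand,
                    f"ID={mrna_id}.cds;Parent={mrna_id}", phase=str(phases[(s, e)]))
            )
        for s, e in g.utr5:
            lines.append(
                row(g.chrom, "five_prime_UTR", s, e, g.strand, f"Parent={mrna_id}")
            )
        for s, e in g.utr3:
            lines.append(
                row(g.chrom, "three_prime_UTR", s, e, g.strand, f"Parent={mrna_id}")
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse the subset of GFF3 this pipeline writes back into gene models."""
    genes: dict[str, dict] = {}
    parent_gene: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, s1, e1, _, strand, _, attrs = line.split("\t")
        s, e = int(s1) - 1, int(e1)
        kv = dict(p.split("=", 1) for p in attrs.split(";") if "=" in p)
        if ftype == "gene":
            genes[kv["ID"]] = {
                "chrom": chrom, "start": s, "end": e, "strand": strand,
                "exons": [], "cds": [], "utr5": [], "utr3": [],
            }
        elif ftype == "mRNA":
            parent_gene[kv["ID"]] = kv["Parent"]
        else:
            gid = parent_gene.get(kv.get("Parent", ""), kv.get("Parent", ""))
            if gid not in genes:
                continue
            key = {
                "exon": "exons", "CDS": "cds",
                "five_prime_UTR": "utr5", "three_prime_UTR": "utr3",
            }.get(ftype)
            if key:
                genes[gid][key].append((s, e))
    return [
        GeneModel(
            gene_id=gid, chrom=g["chrom"], start=g["start"], end=g["end"],
            strand=g["strand"], exons=tuple(sorted(g["exons"])),
            cds=tuple(sorted(g["cds"])), utr5=tuple(sorted(g["utr5"])),
            utr3=tuple(sorted(g["utr3"])),
        )
        for gid, g in genes.items()
    ]


def write_calls(calls: list[CallRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": c.chrom, "pos": c.pos + 1, "ref": c.ref, "alt": c.alt,
                "type": c.kind, "length": c.length, "depth": c.depth,
                "quality": c.quality, "reads_ref": c.reads_ref,
                "reads_alt": c.reads_alt,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path, cultivar: str = "?") -> list[CallRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CallRecord(
            cultivar=cultivar, chrom=str(r.chrom), pos=int(r.pos) - 1,
            ref=str(r.ref), alt=str(r.alt), kind=str(r.type),
            length=int(r.length), depth=int(r.depth), quality=float(r.quality),
            reads_ref=int(r.reads_ref), reads_alt=int(r.reads_alt),
        )
        for r in df.itertuples()
    ]


def write_ssr_table(loci: list[SSRLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "seq_id": l.seq_id, "start": l.start + 1, "end": l.end,
                "motif": l.motif, "canonical_motif": l.canonical_motif,
                "repeats": l.repeat_count, "length": l.total_length,
                "class": l.ssr_class,
            }
            for l in loci
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_ssr_table(path: str | Path) -> list[SSRLocus]:
    df = pd.read_csv(path, sep="\t")
    return [
        SSRLocus(
            seq_id=str(r.seq_id), start=int(r.start) - 1, end=int(r.end),
            motif=str(r.motif), canonical_motif=str(r.canonical_motif),
            repeat_count=int(r.repeats), total_length=int(r.length),
            ssr_class=str(getattr(r, "class")),
        )
        for r in df.itertuples()
    ]


def write_markers(markers: list[PolymorphicMarker], path: str | Path) -> None:
    rows = []
    for m in markers:
        rows.append(
            {
                "marker_type": m.marker_type, "chrom": m.chrom, "pos": m.pos + 1,
                "detail": ";".join(f"{k}={v}" for k, v in sorted(m.detail.items())),
                "flank_ok": m.flank_ok, "feature": m.feature,
                "gene_id": m.gene_id or ".", "coding_effect": m.coding_effect,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_panel(panel: GenotypePanel, path: str | Path) -> None:
    """Genotype panel TSV: locus rows, per-sample GT/DP/GQ/AD column groups."""
    rows = []
    for locus in panel.loci:
        row: dict[str, object] = {"locus": locus}
        for s in panel.samples:
            c = panel.calls.get((locus, s))
            if c is None:
                row[f"{s}.GT"] = "./."
                row[f"{s}.DP"] = 0
                row[f"{s}.GQ"] = 0.0
                row[f"{s}.AD"] = "."
            else:
                row[f"{s}.GT"] = "/".join(c.alleles)
                row[f"{s}.DP"] = c.depth
                row[f"{s}.GQ"] = c.quality
                row[f"{s}.AD"] = ",".join(
                    f"{a}:{n}" for a, n in sorted(c.reads_per_allele.items())
                )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t")
    samples = sorted({c.rsplit(".", 1)[0] for c in df.columns if c.endswith(".GT")})
    loci = [str(l) for l in df["locus"]]
    calls: dict[tuple[str, str], PanelCall] = {}
    for _, r in df.iterrows():
        locus = str(r["locus"])
        for s in samples:
            gt = str(r[f"{s}.GT"])
            if gt in ("./.", ".", "nan"):
                continue
            a1, a2 = gt.split("/")
            ad = str(r[f"{s}.AD"])
            reads = (
                {p.split(":")[0]: int(p.split(":")[1]) for p in ad.split(",")}
                if ad not in (".", "nan") else {}
            )
            calls[(locus, s)] = PanelCall(
                alleles=(min(a1, a2), max(a1, a2)),
                depth=int(r[f"{s}.DP"]), quality=float(r[f"{s}.GQ"]),
                reads_per_allele=reads,
            )
    return GenotypePanel(loci=loci, samples=samples, calls=calls)


def write_phylip(distances, labels: list[str], path: str | Path) -> None:
    lines = [f"{len(labels)}"]
    for label, row in zip(labels, distances):
        lines.append(label.ljust(10) + " ".join(f"{x:.6f}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
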