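"""Synthetic genome-pair and genotype-panel generator with planted truth.

Emulates the data regime of a two-cultivar resequencing comparison: one
reference genome with gene models, two diverged cultivar consensus sequences
carrying planted SNPs (with a tunable transition:transversion ratio), short
1-6 bp InDels, and microsatellite repeat-count differences, plus per-cultivar
call tables with simulated depth/quality/per-allele read support, and a
multi-sample biallelic SNP panel with subpopulation structure.

Every planted event is recorded in a :class:`GenomeTruth` ledger so that
downstream detection and classification can be scored exactly.  Planted
events are mutually non-overlapping — a simulator simplification that makes
truth-based recovery testing exact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import ssr as ssr_mod

__all__ = [
    "SimConfig",
    "GeneModel",
    "PlantedSNP",
    "PlantedIndel",
    "PlantedSSRVariant",
    "GenomeTruth",
    "CallRecord",
    "PanelTruth",
    "generate_reference",
    "seed_ssr_loci",
    "derive_cultivar_pair",
    "simulate_genotype_panel",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """All knobs for one simulation run; ``seed`` fixes every random draw."""

    n_chromosomes: int = 2
    chrom_lengths: tuple[int, ...] = (500_000, 500_000)
    gc_fraction: float = 0.38
    n_genes: int = 50
    snp_rate: float = 1e-3
    titv_target: float = 2.0
    indel_rate: float = 1e-4
    indel_len_probs: tuple[float, ...] = (0.51, 0.22, 0.10, 0.07, 0.05, 0.05)
    n_ssr_seeds: int = 50
    ssr_motif_len_probs: tuple[float, ...] = (0.30, 0.35, 0.20, 0.08, 0.04, 0.03)
    ssr_mutation_prob: float = 0.6
    depth_mean: float = 20.0
    qual_mean: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes != len(self.chrom_lengths):
            raise ValueError("chrom_lengths must list one length per chromosome")
        if any(l < 10_000 for l in self.chrom_lengths):
            raise ValueError("chromosomes must be at least 10 kb")
        for name in ("gc_fraction", "snp_rate", "indel_rate", "ssr_mutation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("indel_len_probs", "ssr_motif_len_probs"):
            p = getattr(self, name)
            if len(p) != 6 or abs(sum(p) - 1.0) > 1e-9 or any(x < 0 for x in p):
                raise ValueError(f"{name} must be 6 non-negative values summing to 1")


@dataclass(frozen=True)
class GeneModel:
    """A simulated gene: 5'UTR, spliced CDS with >=1 intron, 3'UTR.

    Coordinates are 0-based half-open on the reference; ``exons`` are in
    genomic order, ``cds`` intervals fall inside exons and concatenate
    (strand-aware) to a length divisible by 3.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class PlantedSNP:
    chrom: str
    pos: int  # 0-based reference position
    ref_base: str
    base_a: str
    base_b: str


@dataclass(frozen=True)
class PlantedIndel:
    chrom: str
    pos: int  # 0-based reference anchor
    kind: str  # "ins" | "del"
    motif: str
    length: int
    cultivar: str  # "A" | "B"


@dataclass(frozen=True)
class PlantedSSRVariant:
    chrom: str
    ref_anchor: int  # 0-based start of the repeat tract in the reference
    motif: str
    repeat_count_ref: int
    repeat_count_a: int
    repeat_count_b: int

    @property
    def length_diff(self) -> int:
        return abs(self.repeat_count_a - self.repeat_count_b) * len(self.motif)


@dataclass
class GenomeTruth:
    """Ledger of everything the simulator planted — the recovery oracle."""

    planted_snps: list[PlantedSNP] = field(default_factory=list)
    planted_indels: list[PlantedIndel] = field(default_factory=list)
    planted_ssr_variants: list[PlantedSSRVariant] = field(default_factory=list)
    gene_models: list[GeneModel] = field(default_factory=list)


@dataclass(frozen=True)
class CallRecord:
    """One variant call as a caller would report it, with confidence fields."""

    cultivar: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    kind: str  # "snp" | "ins" | "del"
    length: int
    depth: int
    quality: float
    reads_ref: int
    reads_alt: int


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A CDS of ``n_codons`` codons: ATG, internal non-stop codons, one stop."""
    codons = ["ATG"]
    for _ in range(n_codons - 2):
        while True:
            c = "".join(rng.choice(_BASES, size=3))
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append(["TAA", "TAG", "TGA"][rng.integers(3)])
    return "".join(codons)


def generate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], np.random.Generator]:
    """Build reference chromosomes and non-overlapping gene models.

    Returns ``(sequences, genes, rng)`` where ``rng`` carries the stream
    forward for subsequent stages (sub-seeded deterministically from
    ``config.seed``).
    """
    root = np.random.SeedSequence(config.seed)
    ss_ref, ss_rest = root.spawn(2)
    rng = np.random.default_rng(ss_ref)
    sequences: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for i, length in enumerate(config.chrom_lengths):
        name = f"chr{i + 1}"
        arrays[name] = _random_sequence(rng, length, config.gc_fraction)

    genes: list[GeneModel] = []
    if config.n_genes > 0:
        # distribute genes across chromosomes proportional to length
        lengths = np.array(config.chrom_lengths, dtype=float)
        per_chrom = np.floor(lengths / lengths.sum() * config.n_genes).astype(int)
        while per_chrom.sum() < config.n_genes:
            per_chrom[int(np.argmax(lengths - per_chrom))] += 1
        gid = 0
        for ci, name in enumerate(arrays):
            n_here = int(per_chrom[ci])
            if n_here == 0:
                continue
            chrom_len = config.chrom_lengths[ci]
            # gene footprint: utr5 + exon1 + intron + exon2 + utr3
            slot = chrom_len // n_here
            for k in range(n_here):
                utr5_len = int(rng.integers(60, 150))
                utr3_len = int(rng.integers(80, 200))
                n_codons = int(rng.integers(60, 200))
                cds_len = 3 * n_codons
                split = 3 * int(rng.integers(10, n_codons - 10))
                intron_len = int(rng.integers(80, 400))
                footprint = utr5_len + cds_len + intron_len + utr3_len
                margin = slot - footprint - 400
                if margin <= 0:
                    raise ValueError(
                        f"gene models do not fit on {name}: need {footprint + 400} bp "
                        f"per gene slot, have {slot}"
                    )
                start = slot * k + 200 + int(rng.integers(margin))
                strand = "+" if rng.random() < 0.5 else "-"
                cds_seq = _random_cds(rng, n_codons)
                gene = _layout_gene(
                    f"gene{gid + 1:04d}", name, start, strand,
                    utr5_len, cds_len, split, intron_len, utr3_len,
                )
                _write_cds(arrays[name], gene, cds_seq)
                genes.append(gene)
                gid += 1

    sequences = {name: "".join(arr) for name, arr in arrays.items()}
    return sequences, genes, np.random.default_rng(ss_rest)


def _layout_gene(
    gene_id: str, chrom: str, start: int, strand: str,
    utr5_len: int, cds_len: int, split: int, intron_len: int, utr3_len: int,
) -> GeneModel:
    """Place gene parts on the genome.

    In transcript order the gene is UTR5, CDS part 1, intron, CDS part 2,
    UTR3.  On the minus strand that order runs right-to-left on the genome.
    """
    cds1, cds2 = split, cds_len - split
    if strand == "+":
        p = start
        utr5 = (p, p + utr5_len); p += utr5_len
        c1 = (p, p + cds1); p += cds1
        p += intron_len
        c2 = (p, p + cds2); p += cds2
        utr3 = (p, p + utr3_len); p += utr3_len
        end = p
        exon1 = (utr5[0], c1[1])
        exon2 = (c2[0], utr3[1])
        cds = (c1, c2)
    else:
        p = start
        utr3 = (p, p + utr3_len); p += utr3_len
        c2 = (p, p + cds2); p += cds2
        p += intron_len
        c1 = (p, p + cds1); p += cds1
        utr5 = (p, p + utr5_len); p += utr5_len
        end = p
        exon1 = (utr3[0], c2[1])
        exon2 = (c1[0], utr5[1])
        cds = (c2, c1)  # genomic order
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        exons=(exon1, exon2), cds=cds,
        utr5=(utr5,), utr3=(utr3,),
    )


def _write_cds(arr: np.ndarray, gene: GeneModel, cds_seq: str) -> None:
    """Overwrite the reference with the generated CDS bases (strand-aware)."""
    if gene.strand == "-":
        cds_seq = _revcomp(cds_seq)
    # genomic-order CDS intervals receive the (genome-strand) CDS sequence
    offset = 0
    for s, e in gene.cds:
        arr[s:e] = list(cds_seq[offset : offset + (e - s)])
        offset += e - s


# ---------------------------------------------------------------------------
# SSR seeding
# ---------------------------------------------------------------------------


def _random_motif(rng: np.random.Generator, length: int) -> str:
    while True:
        m = "".join(rng.choice(_BASES, size=length))
        if not ssr_mod.is_periodic(m):
            return m


def seed_ssr_loci(
    sequences: dict[str, str],
    genes: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
    truth: GenomeTruth | None = None,
) -> tuple[dict[str, str], GenomeTruth]:
    """Insert perfect SSR arrays into the reference, recording truth.

    Each seeded locus is a perfect tandem repeat of a non-periodic 1-6 bp
    motif, long enough to clear the detection minimum for its motif class
    with two repeat units of headroom (so a one-unit contraction stays
    detectable).  Seeds are >= 400 bp apart, >= 200 bp from contig ends, and
    outside gene bodies; they overwrite reference bases in place (sequence
    length is unchanged).
    """
    truth = truth or GenomeTruth(gene_models=list(genes))
    gene_spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_spans.setdefault(g.chrom, []).append((g.start, g.end))

    arrays = {name: np.array(list(seq)) for name, seq in sequences.items()}
    chrom_names = list(sequences)
    lengths = np.array([len(sequences[c]) for c in chrom_names], dtype=float)
    placed: dict[str, list[int]] = {c: [] for c in chrom_names}
    motif_lens = np.arange(1, 7)

    n_placed = 0
    attempts = 0
    max_attempts = config.n_ssr_seeds * 200
    while n_placed < config.n_ssr_seeds:
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_ssr_seeds} SSR seeds after "
                f"{max_attempts} attempts; genome too small or too crowded"
            )
        attempts += 1
        ci = int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
        chrom = chrom_names[ci]
        mlen = int(rng.choice(motif_lens, p=np.asarray(config.ssr_motif_len_probs)))
        motif = _random_motif(rng, mlen)
        min_units = -(-ssr_mod.DEFAULT_MIN_LENGTHS[mlen] // mlen)  # ceil
        units = min_units + 2 + int(rng.integers(0, 6))
        tract = units * mlen
        lo, hi = 200, int(lengths[ci]) - 200 - tract
        if hi <= lo:
            continue
        anchor = int(rng.integers(lo, hi))
        if any(abs(anchor - a) < 400 + tract for a in placed[chrom]):
            continue
        if any(
            s - 200 < anchor < e + 200 for s, e in gene_spans.get(chrom, [])
        ):
            continue
        arr = arrays[chrom]
        arr[anchor : anchor + tract] = list(motif * units)
        # clip boundary bases so the planted run is maximal exactly as planted
        if arr[anchor - 1] == motif[-1]:
            arr[anchor - 1] = _other_base(rng, motif[-1])
        if arr[anchor + tract] == motif[0]:
            arr[anchor + tract] = _other_base(rng, motif[0])
        placed[chrom].append(anchor)
        truth.planted_ssr_variants.append(
            PlantedSSRVariant(
                chrom=chrom, ref_anchor=anchor, motif=motif,
                repeat_count_ref=units, repeat_count_a=units, repeat_count_b=units,
            )
        )
        n_placed += 1

    out = {name: "".join(arr) for name, arr in arrays.items()}
    return out, truth


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


# ---------------------------------------------------------------------------
# cultivar pair
# ---------------------------------------------------------------------------


def _cds_lookup(genes: list[GeneModel]) -> dict[str, list[tuple[int, int, GeneModel]]]:
    out: dict[str, list[tuple[int, int, GeneModel]]] = {}
    for g in genes:
        for s, e in g.cds:
            out.setdefault(g.chrom, []).append((s, e, g))
    return out


def _snp_makes_stop(
    seq: str, pos: int, alt: str, cds_iv: list[tuple[int, int, GeneModel]]
) -> bool:
    """Would substituting ``alt`` at ``pos`` create a stop codon in a CDS?"""
    for s, e, g in cds_iv:
        if not (s <= pos < e):
            continue
        # codon index within the spliced CDS
        spliced = []
        for cs, ce in g.cds:
            spliced.append((cs, ce))
        cds_pos = 0
        for cs, ce in spliced:
            if cs <= pos < ce:
                cds_pos += pos - cs
                break
            cds_pos += ce - cs
        cds_seq = "".join(seq[cs:ce] for cs, ce in spliced)
        cds_list = list(cds_seq)
        cds_list[cds_pos] = alt
        mutated = "".join(cds_list)
        if g.strand == "-":
            mutated = _revcomp(mutated)
        for k in range(0, len(mutated) - 3, 3):
            if mutated[k : k + 3] in _STOPS:
                return True
    return False


def derive_cultivar_pair(
    sequences: dict[str, str],
    truth: GenomeTruth,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str], list[CallRecord], list[CallRecord], GenomeTruth]:
    """Plant SNPs, InDels and SSR repeat-count changes; emit consensus + calls.

    Returns ``(cultivar_a, cultivar_b, calls_a, calls_b, truth)``.  SNPs are
    drawn at ``snp_rate`` with transition odds ``titv_target / (1 +
    titv_target)``; InDels at ``indel_rate`` with lengths from
    ``indel_len_probs``; each seeded SSR mutates its repeat count in one
    cultivar with probability ``ssr_mutation_prob``.  All events are mutually
    non-overlapping; InDels and SNPs avoid SSR tracts.  Call tables carry
    Poisson depth, clipped-Gaussian quality and per-allele read counts
    (cultivar consensus differences are homozygous, so alternate-allele reads
    take the whole depth).
    """
    cds_iv = _cds_lookup(truth.gene_models)
    p_ti = config.titv_target / (1.0 + config.titv_target)

    # reserved base positions per chromosome (events may not overlap)
    reserved: dict[str, set[int]] = {c: set() for c in sequences}

    def reserve(chrom: str, s: int, e: int) -> None:
        reserved[chrom].update(range(s, e))

    for v in truth.planted_ssr_variants:
        tract = v.repeat_count_ref * len(v.motif)
        # generous pad: repeat-count edits shift downstream bases
        reserve(v.chrom, v.ref_anchor - 8, v.ref_anchor + tract + 8)
    # also keep SNPs/InDels out of naturally occurring repeat runs (and runs
    # just below the detection minimum), so no event masquerades as an SSR
    # length polymorphism
    relaxed = {k: max(v - 3, 2 * k) for k, v in ssr_mod.DEFAULT_MIN_LENGTHS.items()}
    for chrom, seq in sequences.items():
        for locus in ssr_mod.find_ssrs(seq, chrom, relaxed):
            reserve(chrom, locus.start - 8, locus.end + 8)

    def free(chrom: str, s: int, e: int) -> bool:
        return not any(p in reserved[chrom] for p in range(s, e))

    snps: list[PlantedSNP] = []
    indels: list[PlantedIndel] = []

    for chrom, seq in sequences.items():
        L = len(seq)
        n_snp = rng.binomial(L, config.snp_rate)
        n_indel = rng.binomial(L, config.indel_rate)
        # SNPs
        placed = 0
        guard = 0
        while placed < n_snp and guard < n_snp * 50 + 1000:
            guard += 1
            pos = int(rng.integers(10, L - 10))
            if not free(chrom, pos, pos + 1):
                continue
            ref = seq[pos]
            if ref == "N":
                continue
            if rng.random() < p_ti:
                alt = _TRANSITION[ref]
            else:
                alt = _TRANSVERSIONS[ref][int(rng.integers(2))]
            if _snp_makes_stop(seq, pos, alt, cds_iv.get(chrom, [])):
                continue
            cultivar = "A" if rng.random() < 0.5 else "B"
            snps.append(
                PlantedSNP(
                    chrom=chrom, pos=pos, ref_base=ref,
                    base_a=alt if cultivar == "A" else ref,
                    base_b=alt if cultivar == "B" else ref,
                )
            )
            reserve(chrom, pos, pos + 1)
            placed += 1
        if placed < n_snp:
            raise ValueError(
                f"could not place {n_snp} SNPs on {chrom}; attempted density too high"
            )
        # InDels
        placed = 0
        guard = 0
        while placed < n_indel and guard < n_indel * 50 + 1000:
            guard += 1
            length = 1 + int(rng.choice(6, p=np.asarray(config.indel_len_probs)))
            pos = int(rng.integers(10, L - 10 - length))
            if not free(chrom, pos - 1, pos + length + 1):
                continue
            kind = "ins" if rng.random() < 0.5 else "del"
            cultivar = "A" if rng.random() < 0.5 else "B"
            if kind == "del":
                motif = seq[pos : pos + length]
            else:
                motif = "".join(rng.choice(_BASES, size=length))
            if "N" in motif:
                continue
            indels.append(
                PlantedIndel(
                    chrom=chrom, pos=pos, kind=kind, motif=motif,
                    length=length, cultivar=cultivar,
                )
            )
            reserve(chrom, pos - 1, pos + length + 1)
            placed += 1
        if placed < n_indel:
            raise ValueError(
                f"could not place {n_indel} InDels on {chrom}; attempted density too high"
            )

    # SSR mutations
    new_ssrs: list[PlantedSSRVariant] = []
    for v in truth.planted_ssr_variants:
        ca, cb = v.repeat_count_ref, v.repeat_count_ref
        if rng.random() < config.ssr_mutation_prob:
            mlen = len(v.motif)
            min_units = -(-ssr_mod.DEFAULT_MIN_LENGTHS[mlen] // mlen)
            delta = int(rng.integers(1, 3))  # 1 or 2 repeat units
            if rng.random() < 0.5 and v.repeat_count_ref - delta >= min_units:
                delta = -delta
            if rng.random() < 0.5:
                ca = v.repeat_count_ref + delta
            else:
                cb = v.repeat_count_ref + delta
        new_ssrs.append(dataclasses.replace(v, repeat_count_a=ca, repeat_count_b=cb))
    truth.planted_ssr_variants = new_ssrs
    truth.planted_snps = sorted(snps, key=lambda s: (s.chrom, s.pos))
    truth.planted_indels = sorted(indels, key=lambda s: (s.chrom, s.pos))

    cultivar_a = apply_truth(sequences, truth, "A")
    cultivar_b = apply_truth(sequences, truth, "B")

    calls_a = _make_calls("A", truth, config, rng)
    calls_b = _make_calls("B", truth, config, rng)
    return cultivar_a, cultivar_b, calls_a, calls_b, truth


def apply_truth(
    sequences: dict[str, str], truth: GenomeTruth, cultivar: str
) -> dict[str, str]:
    """Reconstruct a cultivar consensus purely from reference + truth ledger.

    Used both to emit the consensus FASTA and, independently, as the oracle
    that every cultivar/reference difference is attributable to one truth
    entry.
    """
    out: dict[str, str] = {}
    for chrom, seq in sequences.items():
        edits: list[tuple[int, int, str]] = []  # (start, end, replacement)
        for s in truth.planted_snps:
            if s.chrom != chrom:
                continue
            base = s.base_a if cultivar == "A" else s.base_b
            if base != s.ref_base:
                edits.append((s.pos, s.pos + 1, base))
        for d in truth.planted_indels:
            if d.chrom != chrom or d.cultivar != cultivar:
                continue
            if d.kind == "del":
                edits.append((d.pos, d.pos + d.length, ""))
            else:
                edits.append((d.pos, d.pos, d.motif))
        for v in truth.planted_ssr_variants:
            units = v.repeat_count_a if cultivar == "A" else v.repeat_count_b
            if v.chrom != chrom or units == v.repeat_count_ref:
                continue
            tract_end = v.ref_anchor + v.repeat_count_ref * len(v.motif)
            edits.append((v.ref_anchor, tract_end, v.motif * units))
        edits.sort(key=lambda e: e[0], reverse=True)
        s = seq
        for start, end, repl in edits:
            s = s[:start] + repl + s[end:]
        out[chrom] = s
    return out


def _confidence(
    rng: np.random.Generator, config: SimConfig
) -> tuple[int, float, int, int]:
    depth = int(rng.poisson(config.depth_mean))
    quality = float(np.clip(rng.normal(config.qual_mean, 5.0), 0.0, 60.0))
    # homozygous consensus difference: all reads support the alternate allele
    return depth, round(quality, 1), 0, depth


def _make_calls(
    cultivar: str, truth: GenomeTruth, config: SimConfig, rng: np.random.Generator
) -> list[CallRecord]:
    calls: list[CallRecord] = []
    for s in truth.planted_snps:
        base = s.base_a if cultivar == "A" else s.base_b
        if base == s.ref_base:
            continue
        depth, qual, r_ref, r_alt = _confidence(rng, config)
        calls.append(
            CallRecord(
                cultivar=cultivar, chrom=s.chrom, pos=s.pos, ref=s.ref_base,
                alt=base, kind="snp", length=0, depth=depth, quality=qual,
                reads_ref=r_ref, reads_alt=r_alt,
            )
        )
    for d in truth.planted_indels:
        if d.cultivar != cultivar:
            continue
        depth, qual, r_ref, r_alt = _confidence(rng, config)
        calls.append(
            CallRecord(
                cultivar=cultivar, chrom=d.chrom, pos=d.pos,
                ref=d.motif if d.kind == "del" else "-",
                alt="-" if d.kind == "del" else d.motif,
                kind=d.kind, length=d.length, depth=depth, quality=qual,
                reads_ref=r_ref, reads_alt=r_alt,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


# ---------------------------------------------------------------------------
# genotype panel
# ---------------------------------------------------------------------------


@dataclass
class PanelTruth:
    """Subpopulation labels and the allele frequencies genotypes were drawn from."""

    sample_labels: list[str]
    subpop_of: dict[str, str]
    freqs: dict[str, np.ndarray]  # subpop -> per-locus frequency of allele 1


def simulate_genotype_panel(
    n_samples: int,
    n_loci: int,
    subpop_spec: dict[str, tuple[int, np.ndarray]] | None = None,
    seed: int = 0,
    depth_mean: float = 25.0,
    qual_mean: float = 40.0,
):
    """Simulate a biallelic genotype panel with subpopulation structure.

    ``subpop_spec`` maps subpopulation name -> (n_samples_in_subpop,
    per-locus frequency vector for allele 1).  When omitted, a single
    panmictic population with Uniform(0.1, 0.9) frequencies is used.
    Genotypes are Hardy-Weinberg draws from the subpopulation frequencies.

    Returns ``(panel, panel_truth)`` where ``panel`` is a
    :class:`dualmark.diversity.GenotypePanel`.
    """
    from .diversity import GenotypePanel, PanelCall

    if n_samples < 2 or n_loci < 1:
        raise ValueError("need n_samples >= 2 and n_loci >= 1")
    rng = np.random.default_rng(seed)
    if subpop_spec is None:
        subpop_spec = {"pop1": (n_samples, rng.uniform(0.1, 0.9, size=n_loci))}
    total = sum(n for n, _ in subpop_spec.values())
    if total != n_samples:
        raise ValueError("subpop sizes must sum to n_samples")
    for name, (_, f) in subpop_spec.items():
        f = np.asarray(f, dtype=float)
        if f.shape != (n_loci,) or np.any(f < 0) or np.any(f > 1):
            raise ValueError(f"frequencies for {name} must be {n_loci} values in [0, 1]")

    # biallelic locus alleles: pick two distinct bases per locus
    allele_pairs = []
    for _ in range(n_loci):
        a, b = rng.choice(4, size=2, replace=False)
        allele_pairs.append(("ACGT"[a], "ACGT"[b]))

    samples: list[str] = []
    subpop_of: dict[str, str] = {}
    genotypes: dict[tuple[str, str], PanelCall] = {}
    locus_ids = [f"L{i + 1:04d}" for i in range(n_loci)]
    si = 0
    for pop, (n_pop, freqs) in subpop_spec.items():
        freqs = np.asarray(freqs, dtype=float)
        for _ in range(n_pop):
            label = f"S{si + 1:02d}"
            samples.append(label)
            subpop_of[label] = pop
            si += 1
            for li, locus in enumerate(locus_ids):
                p = freqs[li]
                a1, a2 = allele_pairs[li]
                pair = tuple(
                    a1 if rng.random() < p else a2 for _ in range(2)
                )
                depth = int(rng.poisson(depth_mean))
                qual = float(np.clip(rng.normal(qual_mean, 5.0), 0, 60))
                if pair[0] == pair[1]:
                    reads = {pair[0]: depth}
                else:
                    k = int(rng.binomial(depth, 0.5))
                    reads = {pair[0]: k, pair[1]: depth - k}
                genotypes[(locus, label)] = PanelCall(
                    alleles=(min(pair), max(pair)), depth=depth,
                    quality=round(qual, 1), reads_per_allele=reads,
                )

    panel = GenotypePanel(loci=locus_ids, samples=samples, calls=genotypes)
    ptruth = PanelTruth(
        sample_labels=samples,
        subpop_of=subpop_of,
        freqs={k: np.asarray(v[1], dtype=float) for k, v in subpop_spec.items()},
    )
    return panel, ptruth
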