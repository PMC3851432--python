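"""Genome-scale marker summaries.

Reproduces the standard report shapes for a two-cultivar marker survey:
per-chromosome counts with densities per Mb, 100-kb window tracks,
transition/transversion ratio, nonsynonymous/synonymous ratio, SSR motif
spectra with class I/II splits, InDel length-by-region cross-tabulations
and fraction-in-region percentages.

All printed rounding flows through :func:`round_half_up` (densities to
integers, ratios to 2 d.p., percentages to 1 d.p.) so table reproduction is
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .polymorphism import PolymorphicMarker, classify_substitution

__all__ = [
    "round_half_up",
    "ChromSummary",
    "per_chromosome_table",
    "window_density",
    "titv_ratio",
    "syn_nonsyn_ratio",
    "motif_spectrum",
    "indel_spectrum",
    "fraction_in_region",
    "fold_difference",
]

MOTIF_CLASS_NAMES = {
    1: "Mononucleotide", 2: "Dinucleotide", 3: "Trinucleotide",
    4: "Tetranucleotide", 5: "Pentanucleotide", 6: "Hexanucleotide",
}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero to ``decimals`` places (report convention)."""
    q = Decimal(10) ** -decimals
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if decimals == 0 else v


@dataclass
class ChromSummary:
    chrom: str
    size_mb: float
    n_snps: int
    n_indels: int
    n_ssrs: int
    density_snps: int
    density_indels: int
    density_ssrs: int


def _counts_by_type(markers: list[PolymorphicMarker]) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for m in markers:
        out.setdefault(m.chrom, {"SNP": 0, "InDel": 0, "SSR": 0})
        out[m.chrom][m.marker_type] += 1
    return out


def per_chromosome_table(
    markers: list[PolymorphicMarker] | pd.DataFrame,
    chrom_sizes_mb: dict[str, float],
) -> pd.DataFrame:
    """Per-chromosome marker counts and densities per Mb, plus a totals row.

    ``markers`` may be a marker list or a DataFrame with columns ``chrom``,
    ``n_snps``, ``n_indels``, ``n_ssrs`` (pre-tallied counts, e.g. from a
    printed table).  Densities are integer-rounded; the totals-row density
    uses summed counts over summed sizes.
    """
    if isinstance(markers, pd.DataFrame):
        counts = {
            r["chrom"]: {
                "SNP": int(r["n_snps"]), "InDel": int(r["n_indels"]),
                "SSR": int(r["n_ssrs"]),
            }
            for _, r in markers.iterrows()
        }
    else:
        counts = _counts_by_type(markers)
        unknown = set(counts) - set(chrom_sizes_mb)
        if unknown:
            raise ValueError(f"markers on chromosomes missing from size table: {unknown}")

    rows = []
    for chrom, size in chrom_sizes_mb.items():
        c = counts.get(chrom, {"SNP": 0, "InDel": 0, "SSR": 0})
        rows.append(
            ChromSummary(
                chrom=chrom, size_mb=size,
                n_snps=c["SNP"], n_indels=c["InDel"], n_ssrs=c["SSR"],
                density_snps=int(round_half_up(c["SNP"] / size)),
                density_indels=int(round_half_up(c["InDel"] / size)),
                density_ssrs=int(round_half_up(c["SSR"] / size)),
            )
        )
    total_size = sum(chrom_sizes_mb.values())
    tot = {
        k: sum(getattr(r, f"n_{k}") for r in rows)
        for k in ("snps", "indels", "ssrs")
    }
    rows.append(
        ChromSummary(
            chrom="Total", size_mb=total_size,
            n_snps=tot["snps"], n_indels=tot["indels"], n_ssrs=tot["ssrs"],
            density_snps=int(round_half_up(tot["snps"] / total_size)),
            density_indels=int(round_half_up(tot["indels"] / total_size)),
            density_ssrs=int(round_half_up(tot["ssrs"] / total_size)),
        )
    )
    return pd.DataFrame([vars(r) for r in rows])


def window_density(
    markers: list[PolymorphicMarker],
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    high_snps_per_mb: float = 1000.0,
    low_snps_per_mb: float = 500.0,
) -> pd.DataFrame:
    """Marker counts in non-overlapping ``window``-bp tiles per chromosome.

    The last tile of each chromosome may be short.  SNP tiles are flagged
    high-density (> ``high_snps_per_mb``) or low-density (<
    ``low_snps_per_mb``) after scaling each tile's count to per-Mb units.
    """
    rows = []
    by_chrom: dict[str, list[PolymorphicMarker]] = {}
    for m in markers:
        if m.pos >= chrom_lengths[m.chrom]:
            raise ValueError(f"marker beyond chromosome end: {m.chrom}:{m.pos}")
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, length in chrom_lengths.items():
        n_win = math.ceil(length / window)
        counts = {t: np.zeros(n_win, dtype=int) for t in ("SNP", "InDel", "SSR")}
        for m in by_chrom.get(chrom, []):
            counts[m.marker_type][m.pos // window] += 1
        for w in range(n_win):
            start = w * window
            end = min(start + window, length)
            snp_per_mb = counts["SNP"][w] / ((end - start) / 1e6)
            rows.append(
                {
                    "chrom": chrom, "start": start, "end": end,
                    "n_snps": int(counts["SNP"][w]),
                    "n_indels": int(counts["InDel"][w]),
                    "n_ssrs": int(counts["SSR"][w]),
                    "snps_per_mb": snp_per_mb,
                    "high_density": snp_per_mb > high_snps_per_mb,
                    "low_density": snp_per_mb < low_snps_per_mb,
                }
            )
    return pd.DataFrame(rows)


def titv_ratio(
    snps: list[PolymorphicMarker] | tuple[int, int],
) -> dict:
    """Transition/transversion ratio with percentages.

    Accepts a SNP marker list or a pre-tallied ``(n_transitions,
    n_transversions)`` pair.  The ratio is reported to 2 d.p.; with zero
    transversions the ratio is undefined (None).
    """
    if isinstance(snps, tuple):
        ti, tv = snps
    else:
        ti = tv = 0
        for m in snps:
            sub = m.detail.get("substitution")
            if sub is None:
                if m.detail.get("multiallelic"):
                    continue
                alt = (
                    m.detail["allele_a"]
                    if m.detail["allele_a"] != m.detail["ref"]
                    else m.detail["allele_b"]
                )
                sub = classify_substitution(m.detail["ref"], alt)
            if sub == "transition":
                ti += 1
            else:
                tv += 1
    total = ti + tv
    return {
        "n_transitions": ti,
        "n_transversions": tv,
        "percent_transitions": round_half_up(100.0 * ti / total, 1) if total else 0.0,
        "percent_transversions": round_half_up(100.0 * tv / total, 1) if total else 0.0,
        "ratio": round_half_up(ti / tv, 2) if tv else None,
    }


def syn_nonsyn_ratio(
    coding_snps: list[PolymorphicMarker] | tuple[int, int],
) -> dict:
    """Nonsynonymous/synonymous ratio (2 d.p.) with counts.

    Accepts annotated coding SNPs or a pre-tallied ``(n_nonsynonymous,
    n_synonymous)`` pair.  Zero synonymous substitutions make the ratio
    undefined (None).
    """
    if isinstance(coding_snps, tuple):
        nonsyn, syn = coding_snps
    else:
        syn = sum(1 for m in coding_snps if m.coding_effect == "synonymous")
        nonsyn = sum(1 for m in coding_snps if m.coding_effect == "nonsynonymous")
    return {
        "n_synonymous": syn,
        "n_nonsynonymous": nonsyn,
        "ratio": round_half_up(nonsyn / syn, 2) if syn else None,
    }


_REPEAT_BINS = [4, 5, 6, 7, 8, 9, 10]


def motif_spectrum(ssr_markers: list[PolymorphicMarker]) -> pd.DataFrame:
    """SSR spectrum by motif length: counts, percent, mean tract length,
    repeat-number histogram (4..10, >10) and class I/II split, with totals.

    Tract length and repeat count are taken from the cultivar-A allele side
    (``len_a``/``repeats_a``) when present, else from locus fields.
    """
    rows = []
    per_len: dict[int, list[tuple[int, int, str]]] = {k: [] for k in range(1, 7)}
    for m in ssr_markers:
        d = m.detail
        motif = d["motif"]
        tract = d.get("len_a", d.get("total_length"))
        repeats = d.get("repeats_a", d.get("repeat_count"))
        per_len[len(motif)].append((tract, repeats, d["ssr_class"]))
    total = sum(len(v) for v in per_len.values())
    for mlen in range(1, 7):
        items = per_len[mlen]
        hist = {b: 0 for b in _REPEAT_BINS}
        hist[">10"] = 0
        for _, reps, _ in items:
            if reps > 10:
                hist[">10"] += 1
            elif reps in hist:
                hist[reps] += 1
        rows.append(
            {
                "motif_class": MOTIF_CLASS_NAMES[mlen],
                "count": len(items),
                "percent": round_half_up(100.0 * len(items) / total, 1) if total else 0.0,
                "avg_motif_length": int(round_half_up(np.mean([t for t, _, _ in items])))
                if items else 0,
                **{f"repeats_{b}": hist[b] for b in _REPEAT_BINS},
                "repeats_gt10": hist[">10"],
                "class_I": sum(1 for _, _, c in items if c == "I"),
                "class_II": sum(1 for _, _, c in items if c == "II"),
            }
        )
    totals = {
        "motif_class": "Total",
        "count": total,
        "percent": 100.0 if total else 0.0,
        "avg_motif_length": int(
            round_half_up(
                np.mean([t for v in per_len.values() for t, _, _ in v])
            )
        )
        if total else 0,
        **{
            f"repeats_{b}": sum(r[f"repeats_{b}"] for r in rows)
            for b in _REPEAT_BINS
        },
        "repeats_gt10": sum(r["repeats_gt10"] for r in rows),
        "class_I": sum(r["class_I"] for r in rows),
        "class_II": sum(r["class_II"] for r in rows),
    }
    return pd.DataFrame(rows + [totals])


def indel_spectrum(indel_markers: list[PolymorphicMarker]) -> pd.DataFrame:
    """Signed InDel length (+1..+6 insertions, -1..-6 deletions) by region.

    Rows are signed lengths, columns the four region labels plus a total;
    a final margins row gives per-region totals.
    """
    regions = ["CDS", "UTR", "intron", "intergenic"]
    lengths = list(range(-6, 0)) + list(range(1, 7))
    table = {l: {r: 0 for r in regions} for l in lengths}
    for m in indel_markers:
        sign = 1 if m.detail["kind"] == "ins" else -1
        l = sign * m.detail["length"]
        region = "UTR" if m.feature in ("UTR5", "UTR3") else m.feature
        if region not in regions:
            region = "intergenic"
        table[l][region] += 1
    rows = []
    for l in lengths:
        row = {"length": l, **table[l]}
        row["total"] = sum(table[l].values())
        rows.append(row)
    margins = {"length": "total", **{r: sum(t[r] for t in table.values()) for r in regions}}
    margins["total"] = sum(margins[r] for r in regions)
    return pd.DataFrame(rows + [margins])


def fraction_in_region(
    markers: list[PolymorphicMarker] | tuple[int, int],
    region_set: set[str] | None = None,
) -> float:
    """Percent (1 d.p.) of markers whose feature is in ``region_set``.

    Accepts annotated markers, or a pre-tallied ``(n_in_region, n_total)``
    pair for reproducing printed percentages.
    """
    if isinstance(markers, tuple):
        n_in, n_tot = markers
    else:
        region_set = region_set or set()
        n_tot = len(markers)
        n_in = sum(1 for m in markers if m.feature in region_set)
    return round_half_up(100.0 * n_in / n_tot, 1) if n_tot else 0.0


def fold_difference(a: float, b: float) -> float:
    """max/min fold difference, 1 d.p."""
    if min(a, b) <= 0:
        raise ValueError("fold difference requires positive values")
    return round_half_up(max(a, b) / min(a, b), 1)
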