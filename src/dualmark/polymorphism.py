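"""Cross-cultivar polymorphism classification and SNP confidence filtering.

A SNP call is kept only when its overall depth exceeds 8, its quality score
exceeds 30, and every observed allele is supported by at least 4 uniquely
mapped reads.  An InDel locus (1-6 bp) is polymorphic when the two cultivars'
InDel motif lengths differ by at least 1 bp; an SSR locus is polymorphic when
the two cultivars' repeat-tract lengths differ by at least 2 bp.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from .simulate import CallRecord
from .ssr import SSRLocus, extract_flanks

logger = logging.getLogger(__name__)

__all__ = [
    "PolymorphicMarker",
    "filter_snp_calls",
    "classify_substitution",
    "call_snp_polymorphisms",
    "call_indel_polymorphisms",
    "call_ssr_polymorphisms",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class PolymorphicMarker:
    """One cross-cultivar polymorphism anchored to reference coordinates."""

    marker_type: str  # "SNP" | "InDel" | "SSR"
    chrom: str
    pos: int  # 0-based reference anchor
    detail: dict = field(default_factory=dict)
    flank_ok: bool = True
    feature: str = "unassigned"  # filled by annotate
    gene_id: str | None = None
    coding_effect: str = "n/a"


def filter_snp_calls(
    calls: list[CallRecord],
    min_depth: int = 8,
    min_quality: float = 30.0,
    min_allele_reads: int = 4,
) -> list[CallRecord]:
    """Retain high-confidence SNP calls; ordering preserved.

    Depth and quality thresholds are strict (``depth > min_depth``,
    ``quality > min_quality``); the per-allele read minimum is inclusive and
    applies to every allele with at least one supporting read.
    """
    kept: list[CallRecord] = []
    for c in calls:
        if c.kind != "snp":
            continue
        try:
            depth, qual = c.depth, c.quality
            observed = [r for r in (c.reads_ref, c.reads_alt) if r > 0]
        except AttributeError:
            logger.warning("call missing confidence fields, rejected: %r", c)
            continue
        if depth is None or qual is None:
            logger.warning("call missing confidence fields, rejected: %r", c)
            continue
        if depth > min_depth and qual > min_quality and all(
            r >= min_allele_reads for r in observed
        ):
            kept.append(c)
    return kept


def classify_substitution(ref_base: str, alt_base: str) -> str:
    """Classify a substitution as "transition" or "transversion"."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base == alt_base:
        raise ValueError("identical bases are not a substitution")
    for b in (ref_base, alt_base):
        if b not in "ACGT":
            raise ValueError(f"ambiguous or invalid base {b!r}")
    same_family = (ref_base in _PURINES) == (alt_base in _PURINES)
    return "transition" if same_family else "transversion"


def call_snp_polymorphisms(
    calls_a: list[CallRecord],
    calls_b: list[CallRecord],
    min_depth: int = 8,
    min_quality: float = 30.0,
    min_allele_reads: int = 4,
) -> list[PolymorphicMarker]:
    """High-confidence SNP differences between the two cultivars.

    Each retained call is a position where one cultivar's consensus differs
    from the reference.  Sites called in both cultivars with the same
    alternate allele are shared substitutions, not cultivar-vs-cultivar
    polymorphisms, and are dropped; sites where the cultivars carry two
    different alternate alleles are kept and flagged multi-allelic.
    """
    fa = filter_snp_calls(calls_a, min_depth, min_quality, min_allele_reads)
    fb = filter_snp_calls(calls_b, min_depth, min_quality, min_allele_reads)
    by_pos_a = {(c.chrom, c.pos): c for c in fa}
    by_pos_b = {(c.chrom, c.pos): c for c in fb}
    markers: list[PolymorphicMarker] = []
    for key in sorted(set(by_pos_a) | set(by_pos_b)):
        a, b = by_pos_a.get(key), by_pos_b.get(key)
        chrom, pos = key
        if a is not None and b is not None:
            if a.alt == b.alt:
                continue  # same substitution in both cultivars
            markers.append(
                PolymorphicMarker(
                    marker_type="SNP", chrom=chrom, pos=pos,
                    detail={
                        "ref": a.ref, "allele_a": a.alt, "allele_b": b.alt,
                        "multiallelic": True,
                    },
                )
            )
            continue
        call = a if a is not None else b
        alleles = (
            {"allele_a": call.alt, "allele_b": call.ref}
            if a is not None
            else {"allele_a": call.ref, "allele_b": call.alt}
        )
        markers.append(
            PolymorphicMarker(
                marker_type="SNP", chrom=chrom, pos=pos,
                detail={
                    "ref": call.ref,
                    **alleles,
                    "substitution": classify_substitution(call.ref, call.alt),
                    "multiallelic": False,
                },
            )
        )
    return markers


def call_indel_polymorphisms(
    calls_a: list[CallRecord],
    calls_b: list[CallRecord],
    reference: dict[str, str],
    max_len: int = 6,
    min_diff: int = 1,
    flank_len: int = 195,
) -> list[PolymorphicMarker]:
    """Classify InDel loci as polymorphic between the cultivars.

    InDel calls (1..``max_len`` bp) are matched across cultivars by
    ``(chrom, pos)``; absence of a call counts as length 0.  A locus is
    polymorphic iff the signed motif lengths differ by >= ``min_diff`` bp.
    Flanks of up to ``flank_len`` bp are extracted from the reference and
    their uniqueness flagged.
    """
    def eligible(calls: list[CallRecord]) -> dict[tuple[str, int], CallRecord]:
        out = {}
        for c in calls:
            if c.kind not in ("ins", "del"):
                continue
            if c.chrom not in reference:
                raise ValueError(f"call on unknown chromosome: {c!r}")
            if 1 <= c.length <= max_len:
                out[(c.chrom, c.pos)] = c
        return out

    ia, ib = eligible(calls_a), eligible(calls_b)
    markers: list[PolymorphicMarker] = []
    for key in sorted(set(ia) | set(ib)):
        chrom, pos = key
        a, b = ia.get(key), ib.get(key)

        def signed_len(c: CallRecord | None) -> int:
            if c is None:
                return 0
            return c.length if c.kind == "ins" else -c.length

        la, lb = signed_len(a), signed_len(b)
        if abs(la - lb) < min_diff:
            continue
        call = a if a is not None else b
        seq = reference[chrom]
        left = seq[max(0, pos - flank_len) : pos]
        right_start = pos + (call.length if call.kind == "del" else 0)
        right = seq[right_start : right_start + flank_len]
        unique = seq.count(left) == 1 and seq.count(right) == 1 if left and right else False
        markers.append(
            PolymorphicMarker(
                marker_type="InDel", chrom=chrom, pos=pos,
                detail={
                    "motif": call.alt if call.kind == "ins" else call.ref,
                    "kind": call.kind,
                    "length": call.length,
                    "len_a": la, "len_b": lb,
                    "cultivar": call.cultivar,
                },
                flank_ok=unique,
            )
        )
    return markers


def project_to_reference(
    pos: int, chrom: str, calls: list[CallRecord]
) -> int:
    """Map a cultivar-consensus coordinate back to the reference.

    Uses the cultivar's own InDel call table to accumulate the coordinate
    shift introduced by insertions (+len) and deletions (-len) upstream of
    the position.
    """
    shifts: list[tuple[int, int]] = []  # (cultivar_pos_of_event, delta)
    offset = 0
    for c in sorted(
        (c for c in calls if c.chrom == chrom and c.kind in ("ins", "del")),
        key=lambda c: c.pos,
    ):
        cultivar_pos = c.pos + offset
        delta = c.length if c.kind == "ins" else -c.length
        shifts.append((cultivar_pos, delta))
        offset += delta
    total = 0
    positions = [s[0] for s in shifts]
    for idx in range(bisect.bisect_right(positions, pos)):
        total += shifts[idx][1]
    return pos - total


def _locate_run(seq: str, approx: int, motif: str, tol: int) -> int | None:
    """Find the left-maximal start of a ``motif`` run near ``approx``.

    Searches offsets 0, ±1, ..., ±tol and returns the first position where
    the motif matches exactly and the run cannot be extended leftwards.
    """
    m = len(motif)
    for delta in sorted(range(-tol, tol + 1), key=abs):
        pos = approx + delta
        if pos < 0 or pos + m > len(seq):
            continue
        if seq[pos : pos + m] != motif:
            continue
        if pos >= 1 and seq[pos - 1] == seq[pos - 1 + m] == motif[-1]:
            continue  # extendable leftwards: not the run start
        return pos
    return None


def _ref_run_length(seq: str, anchor: int, motif: str) -> int:
    """Length (bp) of the perfect run of ``motif`` at ``anchor`` in ``seq``."""
    m = len(motif)
    j = anchor
    while seq[j : j + m] == motif:
        j += m
    return j - anchor


def call_ssr_polymorphisms(
    ssrs_a: list[SSRLocus],
    ssrs_b: list[SSRLocus],
    reference: dict[str, str],
    calls_a: list[CallRecord] | None = None,
    calls_b: list[CallRecord] | None = None,
    min_diff: int = 2,
    flank_len: int = 180,
    match_tol: int = 10,
) -> list[PolymorphicMarker]:
    """Classify SSR loci as polymorphic between the cultivars.

    Per-cultivar SSR scans are anchored back to reference coordinates by
    projecting each locus start through the cultivar's InDel call table
    (upstream insertions/deletions shift consensus coordinates).  Loci match
    when chromosome and canonical motif agree and the projected anchors lie
    within ``match_tol`` bp.  A matched pair is polymorphic iff the tract
    lengths differ by >= ``min_diff`` bp.  A locus detected in exactly one
    cultivar is compared against the reference run length at its anchor.
    Ambiguous many-to-many matches are dropped with a warning, never
    mispaired.
    """
    def anchored(
        loci: list[SSRLocus], calls: list[CallRecord] | None
    ) -> list[tuple[int, SSRLocus]]:
        # Walk each chromosome left to right.  Upstream InDel calls are
        # projected out via the call table; upstream repeat-tract length
        # differences (which the call tables do not describe) are
        # accumulated as we pass each locus, by comparing the cultivar
        # tract length with the reference run at the located anchor.
        out = []
        by_chrom: dict[str, list[SSRLocus]] = {}
        for l in loci:
            by_chrom.setdefault(l.seq_id, []).append(l)
        for chrom, ll in by_chrom.items():
            seq = reference[chrom]
            ssr_offset = 0
            for l in sorted(ll, key=lambda x: x.start):
                approx = (
                    project_to_reference(l.start, chrom, calls) if calls else l.start
                ) - ssr_offset
                anchor = _locate_run(seq, approx, l.motif, match_tol)
                if anchor is None:
                    anchor = approx
                else:
                    ssr_offset += l.total_length - _ref_run_length(seq, anchor, l.motif)
                out.append((anchor, l))
        return out

    aa = anchored(ssrs_a, calls_a)
    bb = anchored(ssrs_b, calls_b)

    def keyed(items):
        d: dict[tuple[str, str], list[tuple[int, SSRLocus]]] = {}
        for anchor, l in items:
            d.setdefault((l.seq_id, l.canonical_motif), []).append((anchor, l))
        return d

    ka, kb = keyed(aa), keyed(bb)
    markers: list[PolymorphicMarker] = []
    used_b: set[int] = set()

    for key in sorted(set(ka) | set(kb)):
        chrom, canon = key
        la = sorted(ka.get(key, []))
        lb = sorted(kb.get(key, []))
        matched_b: set[int] = set()
        for anchor_a, locus_a in la:
            candidates = [
                (i, anchor_b, locus_b)
                for i, (anchor_b, locus_b) in enumerate(lb)
                if i not in matched_b and abs(anchor_b - anchor_a) <= match_tol
            ]
            if len(candidates) > 1:
                logger.warning(
                    "ambiguous SSR match at %s:%d (%s), locus dropped",
                    chrom, anchor_a, canon,
                )
                continue
            if candidates:
                i, anchor_b, locus_b = candidates[0]
                matched_b.add(i)
                len_a, len_b = locus_a.total_length, locus_b.total_length
                other = locus_b
            else:
                len_a = locus_a.total_length
                len_b = _ref_run_length(reference[chrom], anchor_a, locus_a.motif)
                other = None
                logger.info(
                    "SSR at %s:%d detected only in cultivar A; compared to "
                    "reference run length %d", chrom, anchor_a, len_b,
                )
            if abs(len_a - len_b) >= min_diff:
                markers.append(
                    _ssr_marker(locus_a, anchor_a, len_a, len_b, reference, flank_len)
                )
        for i, (anchor_b, locus_b) in enumerate(lb):
            if i in matched_b:
                continue
            len_b = locus_b.total_length
            len_a = _ref_run_length(reference[chrom], anchor_b, locus_b.motif)
            logger.info(
                "SSR at %s:%d detected only in cultivar B; compared to "
                "reference run length %d", chrom, anchor_b, len_a,
            )
            if abs(len_a - len_b) >= min_diff:
                markers.append(
                    _ssr_marker(locus_b, anchor_b, len_a, len_b, reference, flank_len)
                )
    markers.sort(key=lambda m: (m.chrom, m.pos))
    return markers


def _ssr_marker(
    locus: SSRLocus, anchor: int, len_a: int, len_b: int,
    reference: dict[str, str], flank_len: int,
) -> PolymorphicMarker:
    seq = reference[locus.seq_id]
    ref_len = _ref_run_length(seq, anchor, locus.motif)
    left = seq[max(0, anchor - flank_len) : anchor]
    right = seq[anchor + ref_len : anchor + ref_len + flank_len]
    unique = bool(left) and bool(right) and seq.count(left) == 1 and seq.count(right) == 1
    return PolymorphicMarker(
        marker_type="SSR", chrom=locus.seq_id, pos=anchor,
        detail={
            "motif": locus.motif,
            "canonical_motif": locus.canonical_motif,
            "len_a": len_a, "len_b": len_b,
            "repeats_a": len_a // len(locus.motif),
            "repeats_b": len_b // len(locus.motif),
            "ssr_class": locus.ssr_class,
        },
        flank_ok=unique,
    )
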