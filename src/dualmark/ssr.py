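"""Perfect microsatellite (SSR) detection and motif canonicalization.

An SSR here is an uninterrupted (perfect) tandem repeat of a 1-6 bp motif.
Detection uses per-motif-length minimum total lengths: 12 bp for mono-, di-
and trinucleotide motifs, 16 bp for tetra-, 20 bp for penta- and 24 bp for
hexanucleotide motifs.  Loci of total length >= 20 bp are the hypervariable
"class I" tracts; shorter qualifying loci (>= 12 and < 20 bp) are "class II".
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DEFAULT_MIN_LENGTHS",
    "CLASS_I_MIN_BP",
    "SSRLocus",
    "find_ssrs",
    "canonical_motif",
    "motif_group_label",
    "extract_flanks",
]

#: Minimum total tract length (bp) required per motif length 1..6.
DEFAULT_MIN_LENGTHS: dict[int, int] = {1: 12, 2: 12, 3: 12, 4: 16, 5: 20, 6: 24}

#: Total length at or above which a locus is class I (hypervariable).
CLASS_I_MIN_BP = 12 + 8  # 20 bp

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class SSRLocus:
    """A perfect tandem repeat on a named sequence.

    Coordinates are 0-based half-open internally; writers emit 1-based
    inclusive positions.
    """

    seq_id: str
    start: int
    end: int
    motif: str
    canonical_motif: str
    repeat_count: int
    total_length: int
    ssr_class: str  # "I" or "II"

    def __post_init__(self) -> None:
        if self.total_length != self.end - self.start:
            raise ValueError("total_length must equal end - start")
        if self.total_length != self.repeat_count * len(self.motif):
            raise ValueError("perfect repeat: total_length = repeats * motif size")


def _smallest_period(motif: str) -> int:
    """Length of the shortest string whose repetition yields ``motif``."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n


def is_periodic(motif: str) -> bool:
    """True if the motif is itself a repetition of a shorter motif (e.g. "AA")."""
    return _smallest_period(motif) < len(motif)


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/strand equivalence class.

    Returns the lexicographically smallest string among all rotations of the
    motif and all rotations of its reverse complement, so that e.g. "GA",
    "AG", "CT" and "TC" all map to "AG".

    Raises ``ValueError`` for periodic motifs (no well-defined repeat unit).
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if is_periodic(motif):
        raise ValueError(f"motif {motif!r} is a repetition of a shorter motif")
    rc = motif.translate(_COMPLEMENT)[::-1]
    candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(candidates)


def motif_group_label(motif: str) -> str:
    """Render the strand-equivalence group as "X/Y", Y = revcomp of X.

    Example: "GA" -> "AG/CT"; self-complementary "CG" -> "CG/CG".
    """
    canon = canonical_motif(motif)
    return f"{canon}/{canon.translate(_COMPLEMENT)[::-1]}"


def _classify(total_length: int) -> str:
    return "I" if total_length >= CLASS_I_MIN_BP else "II"


def find_ssrs(
    sequence: str,
    seq_id: str = "seq",
    min_lengths: dict[int, int] | None = None,
) -> list[SSRLocus]:
    """Report all maximal perfect tandem repeats meeting their length minimum.

    A locus is reported under its shortest period: a poly-A tract is a
    mononucleotide locus, never a dinucleotide "AA" locus.  Runs containing N
    are broken at the N.  Maximal runs are truncated to a whole number of
    repeat units.  Results are sorted by start position, then period.
    """
    mins = DEFAULT_MIN_LENGTHS if min_lengths is None else min_lengths
    seq = sequence.upper()
    n = len(seq)
    bad = set(seq) - _VALID
    if bad:
        offset = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"non-IUPAC character {seq[offset]!r} at offset {offset} in {seq_id}"
        )

    loci: list[SSRLocus] = []
    seen_spans: set[tuple[int, int]] = set()
    for period in range(1, 7):
        i = 0
        while i + period <= n:
            motif = seq[i : i + period]
            if "N" in motif:
                i += 1
                continue
            # extend the run as far as s[k] == s[k - period]
            j = i + period
            while j < n and seq[j] == seq[j - period] and seq[j] != "N":
                j += 1
            run_len = j - i
            # left-maximality: a run extendable leftwards is reported from
            # its true start when the scan reaches it (we skip duplicates)
            if i > 0 and seq[i - 1] == seq[i - 1 + period] and seq[i - 1] != "N":
                i += 1
                continue
            units = run_len // period
            tract = units * period
            if (
                units >= 2
                and tract >= mins[period]
                and not is_periodic(motif)
                and (i, i + tract) not in seen_spans
            ):
                seen_spans.add((i, i + tract))
                loci.append(
                    SSRLocus(
                        seq_id=seq_id,
                        start=i,
                        end=i + tract,
                        motif=motif,
                        canonical_motif=canonical_motif(motif),
                        repeat_count=units,
                        total_length=tract,
                        ssr_class=_classify(tract),
                    )
                )
            # jump past this run for this period (no other maximal run of the
            # same period can start inside it)
            i = max(i + 1, j - period + 1)
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def extract_flanks(
    locus: SSRLocus,
    reference: str,
    flank_len: int = 180,
) -> tuple[str | None, str | None, bool]:
    """Extract ``flank_len`` bases each side of a locus and test uniqueness.

    Returns ``(left, right, unique)``.  ``unique`` is True iff each flank
    occurs exactly once as an exact substring of the whole reference.  A locus
    closer than ``flank_len`` to a contig end yields ``(None, None, False)``
    (unextractable).
    """
    if locus.start < flank_len or locus.end + flank_len > len(reference):
        return None, None, False
    left = reference[locus.start - flank_len : locus.start]
    right = reference[locus.end : locus.end + flank_len]
    unique = reference.count(left) == 1 and reference.count(right) == 1
    return left, right, unique
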