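"""Shared fixtures: small simulated genomes and a brute-force SSR oracle."""

from __future__ import annotations

import pytest
from hypothesis import settings

# deterministic property tests regardless of local hypothesis state
settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from dualmark.simulate import (
    SimConfig,
    derive_cultivar_pair,
    generate_reference,
    seed_ssr_loci,
)
from dualmark.ssr import DEFAULT_MIN_LENGTHS, is_periodic


def brute_force_ssrs(seq: str, min_lengths=None) -> list[tuple[int, int, str]]:
    """Exhaustive SSR enumerator: tests every (start, period, extension).

    Independent of the scanning detector: for every start position and
    period it extends a perfect repeat unit by unit, keeps tracts meeting
    the per-period minimum with a non-periodic motif, requires
    non-extendability on both sides (maximality), and deduplicates identical
    spans.  Returns sorted (start, end, motif) triples.
    """
    mins = DEFAULT_MIN_LENGTHS if min_lengths is None else min_lengths
    seq = seq.upper()
    n = len(seq)
    found = {}
    for start in range(n):
        for period in range(1, 7):
            motif = seq[start : start + period]
            if len(motif) < period or "N" in motif or is_periodic(motif):
                continue
            # extend unit by unit
            units = 1
            while seq[start + units * period : start + (units + 1) * period] == motif:
                units += 1
            tract = units * period
            if units < 2 or tract < mins[period]:
                continue
            # left-maximality: a partial-unit extension leftwards means this
            # start is inside a longer run reported from its true start
            if start > 0 and seq[start - 1] == motif[-1]:
                continue
            end = start + tract
            key = (start, end)
            if key not in found or len(found[key]) > period:
                found[key] = motif
    return sorted((s, e, m) for (s, e), m in found.items())


@pytest.fixture(scope="session")
def small_sim():
    """A 2 x 100 kb simulated genome pair with planted truth (session-wide)."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_lengths=(100_000, 100_000),
        n_genes=12,
        snp_rate=1e-3,
        indel_rate=1e-4,
        n_ssr_seeds=20,
        ssr_mutation_prob=0.6,
        seed=202,
    )
    seqs, genes, rng = generate_reference(cfg)
    seqs, truth = seed_ssr_loci(seqs, genes, cfg, rng)
    cult_a, cult_b, calls_a, calls_b, truth = derive_cultivar_pair(
        seqs, truth, cfg, rng
    )
    return {
        "config": cfg,
        "reference": seqs,
        "genes": genes,
        "truth": truth,
        "cultivar_a": cult_a,
        "cultivar_b": cult_b,
        "calls_a": calls_a,
        "calls_b": calls_b,
    }
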