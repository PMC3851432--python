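"""Mine perfect microsatellites (SSRs) from a sequence.

Minimum tract lengths are 12/12/12/16/20/24 bp for mono- through
hexanucleotide motifs; tracts of 20 bp or more are the hypervariable
class I, 12-19 bp class II.  Motifs are grouped by their canonical form
(lexicographically smallest rotation of the motif or its reverse
complement), so AG, GA, CT and TC all report as AG.
"""

from collections import Counter

from dualmark.simulate import SimConfig, generate_reference, seed_ssr_loci
from dualmark.ssr import find_ssrs

cfg = SimConfig(n_chromosomes=1, chrom_lengths=(150_000,), n_genes=0,
                n_ssr_seeds=30, seed=4)
seqs, genes, rng = generate_reference(cfg)
seqs, _ = seed_ssr_loci(seqs, genes, cfg, rng)

loci = find_ssrs(seqs["chr1"], "chr1")
print(f"found {len(loci)} perfect SSRs in 150 kb")
by_class = Counter(l.ssr_class for l in loci)
print(f"class I (>=20 bp): {by_class['I']}, class II (12-19 bp): {by_class['II']}")
top = Counter(l.canonical_motif for l in loci).most_common(3)
print("most common canonical motifs:", ", ".join(f"{m} x{n}" for m, n in top))
longest = max(loci, key=lambda l: l.total_length)
print(f"longest tract: ({longest.motif}){longest.repeat_count} = "
      f"{longest.total_length} bp at chr1:{longest.start + 1}")
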