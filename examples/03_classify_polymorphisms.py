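"""Classify cross-cultivar SNP, InDel and SSR polymorphisms, scored vs truth.

A marker is polymorphic only where the two cultivars differ from each
other: substitutions shared by both are dropped, InDels must differ by
at least 1 bp (length 1-6 bp), SSR tracts by at least 2 bp.
"""

from dualmark.polymorphism import (
    call_indel_polymorphisms,
    call_snp_polymorphisms,
    call_ssr_polymorphisms,
)
from dualmark.simulate import (
    SimConfig,
    derive_cultivar_pair,
    generate_reference,
    seed_ssr_loci,
)
from dualmark.ssr import find_ssrs

cfg = SimConfig(n_chromosomes=2, chrom_lengths=(200_000, 150_000),
                n_genes=20, n_ssr_seeds=25, seed=11)
ref, genes, rng = generate_reference(cfg)
ref, truth = seed_ssr_loci(ref, genes, cfg, rng)
a, b, calls_a, calls_b, truth = derive_cultivar_pair(ref, truth, cfg, rng)

snps = call_snp_polymorphisms(calls_a, calls_b)
indels = call_indel_polymorphisms(calls_a, calls_b, ref)
ssrs_a = [l for ch, s in a.items() for l in find_ssrs(s, ch)]
ssrs_b = [l for ch, s in b.items() for l in find_ssrs(s, ch)]
ssrs = call_ssr_polymorphisms(ssrs_a, ssrs_b, ref, calls_a, calls_b)

print(f"polymorphic markers: {len(snps)} SNPs, {len(indels)} InDels, "
      f"{len(ssrs)} SSRs")

truth_indels = {(d.chrom, d.pos) for d in truth.planted_indels}
got_indels = {(m.chrom, m.pos) for m in indels}
truth_ssrs = {(v.chrom, v.ref_anchor) for v in truth.planted_ssr_variants
              if v.length_diff >= 2}
got_ssrs = {(m.chrom, m.pos) for m in ssrs}
print(f"InDel recovery vs planted truth: {len(got_indels & truth_indels)}"
      f"/{len(truth_indels)} recovered, "
      f"{len(got_indels - truth_indels)} false positives")
print(f"SSR recovery (tract difference >= 2 bp): "
      f"{len(got_ssrs & truth_ssrs)}/{len(truth_ssrs)} recovered, "
      f"{len(got_ssrs - truth_ssrs)} false positives")
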