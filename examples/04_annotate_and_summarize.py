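"""Annotate markers against gene models and build genome-scale summaries.

Each marker is labelled CDS / UTR / intron / intergenic from the gene
models; CDS SNPs get a strand-aware synonymous/nonsynonymous call.  The
summary operations reproduce the familiar report shapes: a per-chromosome
density table, a transition/transversion breakdown and a window track.
"""

from dualmark.annotate import annotate_markers, build_feature_index
from dualmark.polymorphism import call_snp_polymorphisms
from dualmark.simulate import (
    SimConfig,
    derive_cultivar_pair,
    generate_reference,
    seed_ssr_loci,
)
from dualmark.summarize import per_chromosome_table, titv_ratio, window_density

cfg = SimConfig(n_chromosomes=2, chrom_lengths=(200_000, 150_000),
                n_genes=30, snp_rate=2e-3, n_ssr_seeds=0, seed=6)
ref, genes, rng = generate_reference(cfg)
ref, truth = seed_ssr_loci(ref, genes, cfg, rng)
a, b, calls_a, calls_b, truth = derive_cultivar_pair(ref, truth, cfg, rng)

markers = call_snp_polymorphisms(calls_a, calls_b)
index = build_feature_index(genes)
annotate_markers(markers, index, ref)

from collections import Counter
features = Counter(m.feature for m in markers)
print("SNPs by feature:", dict(features))
effects = Counter(
    m.coding_effect for m in markers if m.coding_effect not in (None, "n/a")
)
print("coding effects:", dict(effects))

sizes_mb = {c: len(s) / 1e6 for c, s in ref.items()}
table = per_chromosome_table(markers, sizes_mb)
print(table.to_string(index=False))

tt = titv_ratio(markers)
print(f"ti/tv = {tt['ratio']} "
      f"({tt['percent_transitions']}% transitions, "
      f"{tt['percent_transversions']}% transversions)")

windows = window_density(markers, {c: len(s) for c, s in ref.items()})
print(f"{len(windows)} x 100 kb windows; "
      f"{int(windows.high_density.sum())} high-density (>1000/Mb), "
      f"{int(windows.low_density.sum())} low-density (<500/Mb)")
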