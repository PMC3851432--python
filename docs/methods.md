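# Methods

This note records the models, detection rules and numerical conventions the
package implements, in enough detail to re-derive every number the test
suite checks.

## 1. Synthetic genome and cultivar pair

The simulator builds a reference of `n_chromosomes` i.i.d. sequences at a
configurable GC fraction (default 0.38, typical of plant euchromatin), then
derives two cultivars A and B by planting three event classes. All
randomness flows from a single integer seed through
`numpy.random.SeedSequence.spawn`, so each stage has an independent,
reproducible stream.

**Gene models.** Each gene is a two-exon model with 5'UTR, spliced CDS and
3'UTR on a uniformly chosen strand. CDS codons are drawn from the 61
non-stop codons with ATG start and a single terminal stop, written
strand-aware, so every model translates cleanly — which makes downstream
synonymous/nonsynonymous calls well-defined.

**SSR seeds.** `n_ssr_seeds` loci (default 50) get a motif of length 1–6
(weighted toward mono/di) and a tract of `minimum + 2..7` units planted at
least 400 bp apart, 200 bp from chromosome ends and 200 bp outside genes.
Boundary bases are adjusted so the planted tract is left- and
right-maximal and therefore exactly recoverable by the detector.

**Planted differences.** SNPs are placed at rate `snp_rate` (default 1e-3)
with the transition probability `titv / (1 + titv)` for a target ti/tv of
2.0; substitutions that would create an in-frame stop are redrawn. InDels
(rate 1e-4) have lengths 1–6 bp with a decreasing length distribution.
Each seeded SSR mutates with probability 0.6 by ±1–2 repeat units in one
cultivar, never dropping below the detection minimum. Events are placed in
non-overlapping positions; natural repeat runs already present in the
background sequence are also reserved (detected at relaxed minima with an
8 bp pad) so no planted event can create or destroy an SSR by accident.
The ledger of planted events is itself an executable oracle: replaying it
over the reference reproduces each cultivar byte-for-byte, which the tests
assert.

**Call model.** Every planted event emits a homozygous variant call with
depth ~ Poisson(20) and quality ~ N(40, 5) clipped to [0, 60], mimicking a
deeply resequenced inbred cultivar. Depth 20 was chosen as a round value
comfortably above all filtering thresholds so that threshold behaviour is
exercised by the tails, not the mean.

## 2. SSR mining

A tract is a perfect SSR when an uninterrupted repetition of a 1–6 bp
motif reaches the minimum total length 12/12/12/16/20/24 bp (mono- to
hexanucleotide), with at least two whole units. Rules:

- runs break at `N`; partial trailing units are truncated to whole units;
- a locus is reported at its shortest period (an AT run is a dinucleotide
  locus, not two interleaved mononucleotide ones), enforced by rejecting
  motifs that are themselves periodic;
- loci are left-maximal (scanning never reports a suffix of a longer run);
- the canonical motif is the lexicographically smallest rotation of the
  motif or its reverse complement, so AG/GA/CT/TC group together;
- class I = total length ≥ 20 bp, class II = 12–19 bp. Under the minima,
  penta- and hexanucleotide loci are always class I.

The test suite equates the scanner with an exhaustive brute-force
enumerator on 1,000 random 300 bp strings and a battery of adversarial
near-repeats.

## 3. Polymorphism classification

**SNPs** pass confidence filtering at depth > 8, quality > 30 and ≥ 4
reads per observed allele (an unobserved allele is exempt); the first two
are strict inequalities, the read support inclusive. A site is polymorphic
when the filtered alleles of A and B differ; identical substitutions in
both cultivars are dropped, and sites with three observed alleles are kept
but flagged multiallelic.

**InDels** are restricted to 1–6 bp; the signed length difference between
cultivars must be ≥ 1 bp. Flanking sequence (up to 195 bp a side) is
extracted and checked for uniqueness within the reference.

**SSR polymorphisms** require a tract-length difference ≥ 2 bp between
cultivars at the same reference locus; 180 bp flanks are extracted.
Because each cultivar's SSR scan reports coordinates in its own genome,
loci are projected back to reference space: first through the cultivar's
InDel call table (cumulative offsets, binary search), then by walking each
chromosome left-to-right and accumulating the offset contributed by each
SSR tract-length change itself, anchoring each locus with a local
motif-run search around the projected position. This two-stage projection
is what lets the planted-recovery tests demand *exact* position matches.

## 4. Annotation

Gene models are indexed with interval trees; a point query returns the
highest-precedence overlapping feature (CDS > UTR > intron) or
`intergenic`. For a CDS SNP the spliced CDS is reconstructed, the
substitution applied at its transcript offset (reverse-complemented
arithmetic on the minus strand), and both sequences translated; identical
proteins ⇒ synonymous. Genes whose CDS length is not a multiple of three
are flagged and refused rather than guessed at. GO joins count each gene
once per top-level category (biological process, molecular function,
cellular component) and once overall.

## 5. Summaries

- Per-chromosome table: counts and integer densities per Mb; the totals
  row divides summed counts by summed sizes (so it is self-consistent
  even when per-chromosome rounding is not).
- Window track: non-overlapping 100 kb tiles; > 1000 markers/Mb flags a
  high-density window, < 500/Mb low-density.
- Ratios: ti/tv and nonsynonymous/synonymous at 2 decimals; percentages
  at 1 decimal; fold differences (max/min) at 1 decimal.
- All rounding goes through one round-half-up helper (decimal arithmetic,
  not banker's rounding), so printed-table reproduction is deterministic.

## 6. Diversity and clustering

Panel calls are filtered at depth > 15 (strict), quality > 30 (strict)
and ≥ 4 reads per allele. Per locus with ≥ 2 surviving calls:

- allele frequencies `p_i` from allele counts (2 per diploid sample);
- **PIC** = 1 − Σ p_i² — deliberately the simple form, whose biallelic
  maximum is exactly 0.50 at p = 0.5;
- **He** = (2n / (2n − 1)) (1 − Σ p_i²), Nei's unbiased estimator — the
  small-sample correction is why observed He can slightly exceed the PIC
  ceiling (e.g. 12 heterozygous samples give He = 24/23 × 0.5 ≈ 0.522);
- **Ho** = heterozygote fraction; **Na** = distinct alleles.

Samples become a binary presence/absence matrix over (locus, allele)
columns with missing calls masked; similarities (simple matching, Jaccard
or Dice) use pairwise deletion over comparable cells. The dendrogram is
classical neighbor joining on the Q-criterion with deterministic
tie-breaking (lowest index pair after rounding Q to 12 decimals) and
negative branch lengths clamped to zero; on additive matrices it recovers
the generating tree exactly, which the tests check to 1e-9 against both
known trees and an independent library implementation. Newick output
carries 6 decimal places.

## 7. Problem sizes and limitations

Default synthetic scale (2 × 500 kb, ~1,000 SNPs, ~100 InDels, 50 SSR
loci) is chosen so the full planted-recovery suite runs in seconds on one
CPU while still exercising every code path with hundreds of events.
Known simplifications: cultivars are fully homozygous (no heterozygous
calls in the pair comparison); reads are summarized by the call model
rather than simulated; only perfect (uninterrupted) SSRs are mined —
compound and interrupted repeats are out of scope; no recombination,
linkage or genetic-map construction; the genotype panel sampler is
biallelic per locus under Hardy–Weinberg within each subpopulation.
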