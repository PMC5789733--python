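# Methods

## Scope and model

`regcircuits` implements an integrative functional-genomics workflow for
genome–phenome association catalogs (PheWAS- and GWAS-style SNP–trait
tables). The analysis has five layers:

1. **Functional annotation.** Each SNP is classified by genic context
   (exonic / intronic / intergenic, from a user-supplied gene and exon
   model) and by three regulatory categories: overlap with a TF motif
   occurrence, overlap with a promoter or enhancer element, and
   significant cis-eQTL membership (FDR ≤ 0.05, inclusive, in at least
   one tissue). Coding variants additionally receive protein
   functional-site flags: within 2 residues of a ligand-binding site or
   within 7 residues of a phosphorylation site, both inclusive. Summary
   tiers count SNPs with ≥ 1, > 1 and all 3 regulatory categories, under
   both an all-SNP and a noncoding-only denominator (real catalogs are
   ambiguous about which denominator their percentages use, so both are
   reported).
2. **LD extension.** A reported SNP inherits any category carried by a
   proxy in strong LD — r² ≥ 0.8 within 500 kb on either side, both
   thresholds inclusive. Extension is one hop only; proxies of proxies
   are never chased. Extended flags are monotone over base flags by
   construction.
3. **Enrichment.** For each category, a 2×2 table (catalog vs background
   variant set × annotated vs not) is tested with a two-sided Fisher
   exact test, defined as the total hypergeometric probability of all
   tables at the observed margins whose probability does not exceed the
   observed table's (relative slack 1e-7 for floating-point ties — the
   convention of R's `fisher.test` and SciPy). Fold-change is the ratio
   of annotated fractions. For vanishingly small P the log10 P is
   reported alongside, computed in log space, so extreme significances
   never collapse onto an underflow bound. The background is used as-is;
   catalog SNPs are not removed from it. A power stratification cuts the
   catalog into equal-occupancy −log10(P) bins (default 10) and
   correlates the per-bin annotated fraction with the bin midpoint
   (Pearson), probing whether stronger associations are more often
   functional.
4. **Perturbed circuits.** Tissue-specific TF → element → target-gene
   edge lists are taken as input. A SNP perturbs a promoter edge when it
   lies in the promoter span or its 400-bp upstream / 50-bp downstream
   windows (strand-aware; unstranded promoters default to + orientation;
   windows closed on the outer boundary, i.e. the 400th and 50th bp
   count). Enhancer edges are perturbed only by SNPs inside the enhancer
   span — enhancers have no flank. The perturbed circuit for a trait and
   tissue is every network edge through a hit element, each edge
   recording its witnessing SNPs. Circuit gene modules (TFs ∪ targets)
   are compared against a nearest-gene baseline (gene-body distance,
   lexicographic tie-break) by disease-gene enrichment over a gene
   universe, reusing the same exact test. Candidate novel associations
   are flagged by Benjamini–Hochberg FDR (< 0.1) on the raw catalog P
   values.
5. **Tissue specificity.** A gene is tissue-expressed when ≥ 1 RPKM in
   strictly more than 80% of the tissue's samples. The specificity of
   gene *i* in tissue *t* is z(i,t) = (E(i,t) − ⟨E(i)⟩) / δ_E(i), where
   E(i,t) is the mean over the tissue's samples and ⟨E(i)⟩, δ_E(i) are
   the mean and sample (n−1) SD of the per-tissue means across the
   considered tissues. Statistics run on per-tissue means rather than
   pooled samples so unequal sample counts do not weight the grand mean.
   Larger z means higher relative expression in that tissue. δ_E = 0
   yields z = 0 everywhere; no log transform is applied by default
   (`log_transform` switches log1p on).

## Coordinate and I/O conventions

Internal coordinates are 0-based half-open; catalog, eQTL and proxy
tables are 1-based and converted on read; BED is native. Chromosome
names match as exact strings, with an optional "chr"-prefix
normalization pass at read time. All tabular I/O is one TSV dialect
(tab-separated, UTF-8, `#` comments, header row). Readers reject — never
coerce — malformed rows, naming the file and line; a catalog P of
exactly 0 is rejected because downstream works on the log scale.
Writers emit fixed column order, lexicographically sorted rows and
6-significant-digit numbers, so identical inputs give byte-identical
outputs. Nearest-feature distance counts the positions needed to enter
the feature span (an adjacent base is at distance 1); ties break by
distance then lexicographic feature id.

The interval index is a per-chromosome array sorted by start and
augmented with a prefix running maximum of ends (point query = binary
search + bounded walk-back; nearest query = the same containment check
plus start- and end-sorted neighbor lookups). Its contract is equality
with a brute-force linear scan, which the test suite enforces on random
instances and 20-seed acceptance sweeps.

## Synthetic data: what it emulates and what it does not

The generator produces every input the pipeline consumes with planted
ground truth. Each chromosome is cut into equal slots — one
gene-plus-promoter complex, enhancer, or standalone motif per slot, with
800-bp margins — so functional spans and promoter flank windows never
collide across features. Category placement draws SNP positions from
four disjoint pools (motif-only, element-only, motif-inside-enhancer,
neutral), which makes planted category bits exact rather than
approximate. One pseudo-random stream per stage is derived from the
master seed by stage name, so changing one stage's parameters never
perturbs another's draws; a fixed seed reproduces every file byte for
byte.

Default conditions: 1 chromosome of 10 Mb, 200 genes (1.5–3 kb, 2–4
exons of 150 bp, 300-bp stranded promoters abutting the 5′ end), 300
enhancers (300 bp), 500 motif occurrences (12 bp, half inside
enhancers), 5,000 catalog SNPs, 50,000 background SNVs, 4 tissues × 50
samples. Planted catalog category probabilities default to motif 12.6%,
promoter/enhancer 34.8%, eQTL 38.8%, with background levels implying
folds of ≈ 1.33, 1.42 and 14.4 — the regime a PheWAS-scale catalog
exhibits against a whole-genome background. Catalog P values are uniform
on −log10 over (1e-8, 0.05]; a trend slope (default 0.1 per centred
−log10 unit) tilts per-SNP category probabilities so that annotation
rises with association strength while the marginal stays planted.
LD tagging gives each unannotated catalog SNP a functional proxy at
r² ∈ [0.8, 1] within the window with probability `tagging_prob`
(default 0.5, which lifts ≥ 1-category coverage from ~65% to ~80% on a
default run), plus sub-threshold (r² < 0.8) and beyond-window pairs so
both filters are exercised. Promoter edges target their own gene;
enhancer edges deliberately target distal genes (never the enhancer's
nearest gene) so circuit modules and nearest-gene modules genuinely
differ. Witness SNPs for the planted perturbed edges cycle through
promoter bodies and the exact 400-bp/50-bp flank boundary positions on
both strands, plus enhancer bodies. Expression is log-normal (log-mean
0.7, log-SD 0.6, tissue offset 0.15, sample noise 0.4 — most genes clear
the RPKM ≥ 1 rule); planted tissue-specific genes have the spiked
tissue's mean set to the mean of the other tissues' means plus 4 of
their SDs. Disease genes are drawn with a configurable excess on circuit
target genes (default fraction 0.8 of the list, capped by the number of
targets).

The generator does **not** emulate realistic human LD block structure,
allele frequencies, mutation models, overlapping or nested regulatory
elements, genome-build differences, or expression batch effects. Passing
recovery tests therefore demonstrates that the pipeline's logic is
correct and its thresholds act exactly as specified — not that the
statistical conclusions transfer to any particular real catalog.

## Numerical choices and degenerate inputs

- Fisher test: any zero margin raises; P values computed via
  log-gamma; tie comparison uses the 1e-7 relative slack; the
  exhaustive integer-arithmetic oracle in the tests agrees to < 1e-13
  relative error over all ~630k tables with total ≤ 60.
- Fold-change is NA when the background count is 0; recovery checks use
  a 99% CI from the log-ratio normal approximation.
- Stratification requires ≥ 2 bins and ≥ 5 records per bin; a constant
  annotated fraction reports r = 0, p = 1.
- Duplicate (SNP, trait) catalog rows collapse to the smallest P;
  duplicate LD pairs keep the larger r².
- Empty annotation input yields an all-zero summary; an empty gene
  model classifies everything intergenic; a SNP on a chromosome without
  genes is skipped (and reported) by the nearest-gene baseline.
- Circuit trait inclusion requires the association P strictly below
  `circuit_p` (default 0.05).

## Design decisions that were genuinely open

- **Denominator of category percentages**: both all-SNP and
  noncoding-only modes are emitted rather than guessing one.
- **Nearest gene** is measured to the gene body, not the TSS.
- **Background handling**: catalog SNPs are not removed from the
  background set; the choice is recorded in the manifest.
- **Two-sided** test everywhere (the R default convention).
- **z-score direction**: larger z = higher expression in the tissue;
  this follows the defining formula directly.
- **Promoter flanks closed on the outer boundary**: "400 bp upstream to
  50 bp downstream" is read as inclusive spans.
- **No log transform before the z-score** by default, exposed as a
  switch.

## Problem sizes used in the test suite

Unit tests run on toy fixtures and a shared small simulation (2 Mb, 50
genes, 600 catalog / 3,000 background SNPs). The acceptance-style tests
use the full default conditions: the exhaustive Fisher sweep covers all
~630k tables with n ≤ 60; interval-oracle sweeps use 10⁴ intervals ×
1,000 queries × 20 seeds; fold recovery uses 5,000/50,000 variants × 4
folds × 20 seeds; circuit, z-score and module-comparison recoveries use
20 seeds each at default scale. The module-comparison "strong excess"
condition plants a 24-edge circuit with a 20-gene disease list
concentrated on its targets; the null condition sets the excess to zero.

## Known limitations

- The genic classifier is deliberately minimal (exon/intron/intergenic);
  no splice, UTR or transcript-aware subcategories.
- Motif occurrences are taken as provided intervals; no PWM scanning or
  binding-affinity change prediction from alleles.
- LD comes only from the pair table; r² is never computed from
  genotypes, and no population panels are modelled.
- TF → element → target links are inputs, not inferred.
- Enrichment is overlap-based; no LD-aware or covariate-matched
  background correction.
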