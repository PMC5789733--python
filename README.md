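# regcircuits

Functional interpretation of genome–phenome association catalogs:
annotate disease-associated SNPs with regulatory evidence, propagate
annotations through LD proxies, quantify enrichment against a background
variant set, reconstruct tissue-specific perturbed TF–promoter/enhancer–
target circuits, and score the tissue specificity of circuit genes.

Most variants that PheWAS and GWAS report sit in non-coding sequence,
where their mechanism is invisible to the association statistics alone.
`regcircuits` is for analysts who have a SNP–trait catalog and want to
ask, reproducibly: which of these variants fall in TF motifs, promoters
or enhancers, or act as cis-eQTLs (FDR ≤ 0.05)? Does that remain true
once strong-LD proxies (r² ≥ 0.8 within 500 kb) are allowed to carry the
evidence? Are those categories enriched relative to background variation,
and does enrichment grow with association strength? And which
tissue-specific TF → element → target edges do the variants perturb —
counting a promoter hit anywhere from 400 bp upstream to 50 bp downstream
of the promoter, and an enhancer hit only inside the enhancer body?

The statistics at the core:

- **Enrichment** — two-sided Fisher exact test on the 2×2 table
  (catalog vs background × annotated vs not), P = Σ Pr(T) over all
  tables T at the observed margins with Pr(T) ≤ Pr(observed); fold
  change = (a/(a+b)) / (c/(c+d)); log10 P reported exactly even when P
  underflows doubles.
- **Tissue specificity** — z(i,t) = (E(i,t) − ⟨E(i)⟩) / δ_E(i), with
  ⟨E⟩ and the (n−1) SD taken across per-tissue mean expressions; a gene
  is tissue-expressed at RPKM ≥ 1 in > 80% of samples.
- **Novel-association screening** — Benjamini–Hochberg q-values on the
  raw catalog P, flagging q < 0.1.

A first-class synthetic-data generator emits every input file with
planted ground truth (category probabilities and folds, LD taggings,
perturbed edges, tissue-specific genes, disease-gene placement), so the
entire pipeline is testable end to end without downloading anything.

## Worked example

Simulate a default study (one 10-Mb chromosome, 200 genes, 5,000 catalog
SNPs, 50,000 background SNVs, 4 tissues × 50 samples) and run every
stage:

```sh
regcircuits simulate --out sim --seed 1
regcircuits run-all --input sim --out out --seed 1
```

The run log prints one line per stage:

```
[regcircuits] annotate: catalog snps=5006 background snvs=50000
[regcircuits] extend_ld: pairs=960 proxies=960 coverage 3250->4142 of 5006
[regcircuits] enrich: categories=4
[regcircuits] stratify: bins=10 base r=0.968
[regcircuits] circuits: trait=circuit_trait tissue=tissue_01 snps=6 hits=6 edges=8
[regcircuits] expression: genes=200 tissues=4
[regcircuits] compare: circuit log10P=-1.34 nearest log10P=-0.00
[regcircuits] novel: flagged=5006 of 5006
[regcircuits] recovery: all_green=True
```

Reading the numbers: 3,250 of 5,006 catalog SNPs (64.9%) carry at least
one regulatory category directly, rising to 4,142 (82.7%) after LD
extension — unannotated SNPs inherit evidence from their strong-LD
proxies. `out/enrichment.json` holds the category tests; on this seed
the catalog shows 1.28-fold motif, 1.47-fold promoter/enhancer and
14.4-fold eQTL enrichment over the background (log10 P ≈ −8.6, −63.8 and
−1278.9), matching the planted generator folds of 1.33 / 1.42 / 14.4.
The stratification r = 0.968 (p ≈ 4×10⁻⁶) reflects the planted rise of
annotation probability with association strength. The circuit stage
recovers exactly the 8 planted perturbed edges (precision = recall = 1
in `out/recovery.json`), and every planted tissue-specific gene attains
its maximum z-score in the planted tissue.

The same operations are available as a library:

```python
from regcircuits import ContingencyTable, fisher_exact_2x2, tissue_specificity_z

fisher_exact_2x2(ContingencyTable(a=398, b=2709, c=96578, d=903422))  # 1.23e-08
tissue_specificity_z({"brain": 10.0, "lung": 0, "liver": 0, "skin": 0, "blood": 0})
# {'blood': -0.447..., 'brain': 1.788..., ...}
```

Single stages (`annotate`, `extend-ld`, `enrich`, `stratify`,
`circuits`, `expression`, `compare`, `novel`) run individually over the
same directory; `--config` accepts a YAML file of `PipelineConfig` or
`SimulationConfig` fields. All thresholds (eQTL FDR 0.05, r² 0.8, 500-kb
window, 400/50-bp promoter flanks, RPKM ≥ 1 in > 80%, BH FDR 0.1) are
config parameters defaulting to the values above.

## Layout

```
src/regcircuits/
  intervals.py    genome coordinates, interval index (point + nearest queries)
  io.py           strict TSV/BED readers, deterministic writers
  annotate.py     genic context, protein sites, regulatory categories
  ld.py           proxy lookup and annotation extension
  enrichment.py   Fisher exact test, fold changes, power stratification
  circuits.py     SNP->element hits, perturbed circuits, module enrichment
  expression.py   tissue-expressed calls, specificity z-scores
  simulate.py     synthetic inputs with planted ground truth
  pipeline.py     stage orchestration, manifests, recovery report
  cli.py          the `regcircuits` command
```

See `docs/methods.md` for the full model description, conventions,
generator design and limitations.
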