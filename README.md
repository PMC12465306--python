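# salmotx

Post-assembly transcriptome analysis for reference-guided RNA-seq studies of
Atlantic salmon reproductive tissues (gonads and pituitary) — and, more
generally, for any multi-tissue study that starts from a reference
annotation, a merged assembly, a genome, and a gene-level count matrix.

A reference-guided assembly of deeply sequenced tissues produces far more
transcripts than the reference annotation contains. The scientific question
this package addresses is what those extra transcripts are and what they
might do: which assembled transcripts match known gene structures, which are
intergenic, which intergenic loci encode proteins (newly characterized gene
copies) versus long intergenic non-coding RNAs (lincRNAs), which loci are
tissue-specific, how loci organize into co-expression modules, and which
lincRNAs sit close enough to a co-expressed coding gene to suggest
cis-regulation — including divergent, head-to-head pairs that may share a
bi-directional promoter.

## What it computes

| Stage | Statistic / model |
|---|---|
| `salmotx.compare` | gffcompare-style class codes (`=`, `c`, `j`, `e`, `o`, `i`, `x`, `u`) with precedence; assembly sensitivity/precision; per-sample support of intergenic transcripts; cross-dataset intergenic overlap |
| `salmotx.coding` | 3-frame ORF discovery (≥ 100 aa); exact Euler-path k-let shuffle (k = 7) for composition-matched negatives; CPS classifier with ten-fold cross-validated cutoff; locus triage into new coding genes vs lincRNAs |
| `salmotx.position` | nearest-partner annotation by 10–100 kb sliding windows; direction, location, boundary gap and TSS distance |
| `salmotx.expression` | median-of-ratios size factors; NB Wald pairwise DE (log2FC ≥ 2, BH-adjusted p ≤ 0.01); TPM; tissue-specificity index τ = Σ(1 − x̂ᵢ)/(n − 1) with threshold τ > 0.8 |
| `salmotx.network` | unsigned adjacency \|cor\|^β, soft power by scale-free fit R² > 0.8, TOM, module detection (minModuleSize 30, mergeCutHeight 0.25), module eigengenes, module–tissue correlation (r > \|0.7\|, p < 0.01) |
| `salmotx.enrichment` | hypergeometric over-representation with BH FDR < 0.05, top 10 terms |
| `salmotx.pairs` | lincRNA–gene pairs within 100 kb sharing a module; classes: bi-directional promoter (antisense ∧ upstream ∧ TSS < 5 kb), dubious 5′ extension (sense ∧ upstream ∧ < 5 kb), cis-acting |
| `salmotx.synthetic` | complete seeded toy study (genome, annotations, counts) with ground truth for every stage |

The packaged table `salmotx/data/salmon_lincrna_pairs.tsv` holds the 18
published Atlantic salmon candidate lincRNA–gene pairs (coordinates, module,
orientation, distance, τ) used as a fixed input for rule checks.

## Worked example

The `analysis/` directory is a numbered narrative over the library. Running

```
python analysis/01_simulate_study.py --seed 1
python analysis/02_classify_transcripts.py
python analysis/03_triage_intergenic.py
python analysis/04_expression_analysis.py
python analysis/05_coexpression_modules.py
python analysis/06_module_enrichment.py
python analysis/07_prioritize_pairs.py
```

simulates a toy study (454 reference loci, 52 assembled transcripts with
planted class codes, 478 × 48 count matrix over four tissues) and pushes it
through every stage. Selected output:

```
planted codes recovered: 52/52
CPS cutoff 0.805 (10-fold CV sensitivity 1.00, specificity 1.00)
locus categories: {'known_coding': 23, 'lincRNA': 19, 'new_coding': 10}
planted intergenic categories recovered: 24/24
tissue-specific loci (single-tissue upregulated AND tau > 0.8): 100
planted tissue-specific loci recovered: 100/100
module sizes: {'turquoise': 90, 'blue': 89, 'brown': 89, 'yellow': 87, 'grey': 3}
  turquoise: best tissue immature_testis (r=0.90, significant)
  blue: best tissue mature_testis (r=0.93, significant)
candidate pairs (within 100 kb, same module): 4
planted pairs recovered exactly: 4/4
published table check: 5 bi-directional promoter pairs among 18 rows; rule concordance 100%
```

Reading the numbers: every planted transcript class code is recovered by the
classifier; the coding-potential cutoff separates mRNAs from their
7-let-shuffled negatives perfectly in cross-validation; all 24 planted
intergenic loci land in their true category (coding gene vs lincRNA); all
100 planted tissue-specific loci pass both the differential-expression rule
and τ > 0.8; the four planted latent-factor modules are recovered with each
eigengene most correlated with its planted tissue; and all four planted
lincRNA–gene pairs are emitted with their true functional class. The final
line re-applies the promoter rule to the published 18-row candidate table
and reproduces its five bi-directional-promoter pairs.

## Layout

```
src/salmotx/       library (annotation model, compare, coding, position,
                   expression, network, enrichment, pairs, synthetic, pipeline)
analysis/          numbered narrative drivers writing results/
scripts/           acceptance script
tests/             pytest suite with independent brute-force oracles
docs/methods.md    models, parameters, design decisions, limitations
```
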