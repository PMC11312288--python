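# microsig

Comparison of microglial transcriptomic signatures in a WT-vs-AQP4-KO
corpus-callosum study design: differential-expression filtering,
pre-ranked gene-set enrichment, population-signature similarity analysis,
and ΔΔCt qPCR validation — built as a tested, seed-reproducible pipeline
for researchers who want to run or scrutinise this kind of analysis
end to end.

During postnatal myelination of the corpus callosum, a transient CD11c⁺
microglial population appears; in aquaporin-4 knockout mice its presence
is prolonged, with massive overexpression of markers such as *Spp1*,
*Gpnmb* and *Itgax*. Deciding whether such a population matches
neurodevelopmental subtypes (PAM, ATM, CD11c) or disease-associated ones
(DAM, MGnD, LDAM, …) is a signature-comparison problem, which this
package implements. The original arrays are deposited without a standard
accession, so a synthetic-data module emulates the study design with
planted, known ground truth; every statistical property is verified
against that truth.

## The core method

Each microglial population *i* is a signature vector of n′ gene-level
log2 fold-changes on a shared panel. Populations are compared through

- the distance matrix **D**, d(i,j) = ‖i − j‖₂ (the closer, the more
  similar the regulation), and
- the cross-correlation matrix **C**, c(i,j) = |cos θ| = |i·j| / (‖i‖‖j‖)
  ∈ [0, 1], where 0 means no linear relationship and 1 equivalent
  profiles,

followed by classical (Torgerson) MDS of **D** into Cartesian coordinates
and average-linkage hierarchical clustering. Upstream, genes are called
differentially expressed by an empirical-Bayes moderated t with
Benjamini–Hochberg FDR, at the strict filter q < 0.05 and signed linear
fold > 1.5; the signed −log10(p) ranking feeds a weighted running-sum
gene-set enrichment with a gene-set permutation null. qPCR validation
uses the comparative Ct method: ΔΔCt = ΔCt − mean(calibrator ΔCt),
fold = 2^−ΔΔCt, t test on per-animal ΔCt.

## Worked example

The numbered drivers under `analysis/` run the whole study emulation
(seed 11) and write their tables under `results/analysis/`:

```sh
python analysis/01_simulate_fixtures.py
python analysis/02_differential_expression.py
python analysis/03_enrichment.py
python analysis/04_signature_comparison.py
python analysis/05_qpcr_validation.py
```

The differential-expression step prints

```
Significant genes (q < 0.05, |fold| > 1.5): 205 (163 up, 42 down)
Top overexpressed genes:
          fold         p         q
Spp1       720 3.24e-190 6.48e-187
Gpnmb      102 1.18e-129 1.18e-126
Itgax     78.1 2.68e-121 1.78e-118
```

— the filter recovers the planted programme (199 genes planted; Spp1
planted at 600-fold, estimated 720 from three samples per condition) with
a handful of false calls, matching the configured 5% FDR. The signature
comparison prints

```
Cosine cross-correlation of AQP4-CC with selected populations:
  AQP4-CC vs AQP4-AC : 0.89
  AQP4-CC vs CD11c   : 0.89
  AQP4-CC vs PAM     : 0.89
  AQP4-CC vs DAM1    : 0.20
  AQP4-CC vs Aged    : 0.19
2-cluster cut vs planted blocks: ARI = 1.00
```

— the corpus-callosum signature clusters with the neurodevelopment-linked
populations and away from disease/ageing subtypes, exactly as planted
(within-block cosine 0.9, between 0.2, attenuated by noise). The qPCR
step recovers the planted 535-fold Spp1 overexpression as 559 (n = 6 per
group, 0.3-cycle noise).

The same pipeline is available as a CLI (`microsig fixtures/de/enrich/
compare/qpcr/run`); `microsig run --config configs/demo.yaml` executes
all five stages and writes a manifest with per-file SHA-256 hashes that
is bit-identical across reruns.

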