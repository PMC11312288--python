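# Methods

`microsig` re-implements, as a reusable and tested pipeline, the
computational analysis of a WT-vs-AQP4-knockout corpus-callosum
transcriptomics study: differential-expression filtering, pre-ranked
gene-set enrichment, comparison of microglial population signatures via
Euclidean-distance and cosine cross-correlation matrices with classical
MDS and hierarchical clustering, and ΔΔCt qPCR validation. The original
expression data are deposited only at an institutional repository without
a standard accession, so the pipeline is driven by synthetic-data
generators that emulate the published study design; every claim the test
suite makes is therefore a claim about planted, known ground truth.

## Synthetic-data generators

**Expression study.** Genes × samples log2 intensities; per-gene baseline
`N(7, 1.5²)` (log2 units, typical of normalised array intensities),
additive Gaussian noise on the log2 scale (`noise_sd_log2`, default 0.25)
— the standard variance-stabilised approximation for intensity arrays,
chosen because it keeps every planted expectation closed-form. Two
conditions (WT reference, KO test), 3 samples each by default, mirroring
the study's three pooled samples per condition. Planted genes shift the
test-condition mean by `log2(fold)`. The marker genes carry defaults
shaped like the published result: Spp1 600-fold, then Gpnmb 90, Itgax 70,
Atp6v0d2 30, Cd68 25, Igf1 12, Lgals3 8, ApoE 4, Trem2 3. The pipeline's
demo configuration adds 150 background up- and 40 down-regulated genes
with log-uniform folds (1.6–8×), a desk-scale stand-in for the thousands
of calls the real contrast produced. The published noise magnitude is
unknown; 0.25 log2 units was fixed once as a realistic array dispersion
and is the condition under which all calibration properties are stated.

What the generator does *not* emulate: probe-level effects and RMA
preprocessing, batch structure, heteroscedastic (intensity-dependent)
variance, and gene–gene correlation. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to array artefacts.

**Signature collection.** Eleven populations in two planted blocks —
neurodevelopment-linked (AQP4-CC, AQP4-AC, CD11c, PAM, ATM) and
disease/ageing-linked (DAM1, DAM2, MGnD, LDAM, APP, Aged) — over an
`n′ = 500`-gene panel. Construction: draw an orthonormal basis (QR of a
Gaussian matrix); each block direction mixes a shared direction with a
block-specific one so that block cosines equal `between/within`; each
population mixes its block direction with weight `√within` and an
independent basis vector with weight `√(1−within)`. Pre-noise population
cosines then hit the targets *exactly* (within-block `within`,
between-block `between`); entrywise Gaussian noise of total relative
magnitude `noise_sd` (default 0.1) attenuates them by ≈ `1/(1+noise_sd²)`.
Defaults `within = 0.9`, `between = 0.2` put the within-block cosine near
the strongest published cross-population correlations. The construction
needs `n′ ≥ 1 + #blocks + #populations`.

**qPCR plate.** Ct per (gene, group, animal, technical replicate):
reference gene (Rn18s) base Ct 12 cycles, targets 25, a per-animal offset
(SD 0.15 cycles, shared across genes — RNA-input variation that cancels
in ΔCt), planted fold `f` subtracting `log2 f` cycles in the KO group,
and replicate noise (`ct_noise_sd`, default 0.3 cycles). Triplicates and
n = 6 animals per group by default. Simulated Ct values are validated to
lie in (0, 40); the planted fold maps to `ΔΔCt = −log2 f` exactly in
expectation.

All generators draw from named substreams of one user seed (CRC-keyed
`SeedSequence` spawn), so adding a component never changes another's
draws, and identical configs are byte-identical after serialisation.

## Differential expression

Per-gene two-group comparison on the log2 matrix; the significance filter
is strict `q < 0.05` (Benjamini–Hochberg step-up over all genes, via
statsmodels) **and** signed linear fold `|fold| > 1.5`, with
`fold = 2^log2fc` for up- and `−2^(−log2fc)` for down-regulation (the
array-software convention, so the threshold acts symmetrically).

The default test is an **empirical-Bayes moderated t**: per-gene pooled
variances (df `n₁+n₂−2`) are modelled as scaled inverse-χ² draws around a
prior `(d₀, s₀²)` estimated by matching moments of `log s²` (trigamma
inversion by Newton iteration); the posterior variance enters a t
statistic with `d₀ + d` df. At a 3-vs-3 design the unmoderated per-gene t
is so heavy-tailed that even 9-σ planted effects receive median p ≈ 2·10⁻³
and the q/fold filter loses most of them; variance moderation is the
field-standard remedy for exactly this design and restores both
calibration (measured null false-positive rate ≈ 0.047 at α = 0.05) and
power (planted fold-4 genes recovered essentially completely with
realised FDP ≈ 0.05). Plain Welch and pooled-variance Student tests remain
available (`method="welch"/"student"`), and `welch_t_per_gene` handles the
degenerate zero-variance cases explicitly (equal means → p = 1; unequal →
p = 0, logged).

The enrichment ranking is signed `−log10 p` (sign of the fold), p = 0
clipped to 320 and logged, ties broken by gene name so the ordering is
deterministic.

## Gene-set enrichment

Weighted running-sum statistic over the ranked list: hits add
`|score|^w` (normalised to sum 1 over hits; `w = 1` default, `w = 0`
gives the analytically checkable unweighted walk), misses subtract
`1/(N−N_hit)`; ES is the signed extremum, always in [−1, 1]. A set equal
to the whole universe has ES 0 by convention; a set with all-zero hit
scores falls back to uniform hit increments.

The null resamples random gene sets of equal size from the ranked
universe — a gene-set (not phenotype) permutation, because a pre-ranked
3-vs-3 design leaves phenotype permutation no resolution. NES divides ES
by the mean |ES| of same-sign null draws (a warning flag is raised when
fewer than 5 same-sign draws exist). The permutation p compares
magnitudes two-sidedly, `p = (1 + #{|null ES| ≥ |ES|})/(1 + n_perm)`:
this keeps the estimator valid (measured null rate of p ≤ 0.05 ≈ 0.05,
inside [0.03, 0.08]), respects the `1/(n_perm+1)` floor, and gives a
maximally enriched set exactly the minimal p. A one-sided-by-sign
comparison against the full null would double the null rejection rate
(each sign's tail contributes ≈ 5%) and was rejected for that reason.

## Signature comparison

Signatures are log2 fold-changes versus each study's own control,
restricted to a shared panel: fold-change vectors are comparable across
platforms, which is how the published subtype signatures are distributed.
Panels are harmonised by case-insensitive symbol intersection
(complete-case: dropping never fabricates signal), deterministic sorted
order, spelling taken from the first collection.

* `D`: pairwise Euclidean distances (computed via the Gram identity,
  clipped at 0 before the square root, symmetrised, exact-zero diagonal).
* `C`: `|i·j|/(‖i‖‖j‖)` — the modulus is applied exactly as the method
  defines it, so anti-correlated profiles score as similar; a
  `signed=True` flag exposes the signed cosine for sensitivity analysis.
  Zero-magnitude vectors are rejected by population name. For
  unit-normalised vectors with non-negative cosine, `d² = 2(1 − cos θ)`
  ties the two matrices together (property-tested).
* Classical MDS (Torgerson): double-centre `−½D²`, symmetric
  eigendecomposition, coordinates from the top-k eigenpairs with negative
  eigenvalues contributing zero; axis signs fixed by forcing each axis's
  largest-magnitude coordinate positive (eigenvectors are sign-ambiguous
  and outputs must be reproducible). Stress is the relative residual
  `√(Σ(d−d̂)²/Σd²)`, defined as 0 for an all-zero matrix.
* Clustering: hand-rolled average linkage (Lance–Williams update) because
  the required deterministic tie-break — lexicographically smallest pair
  of cluster representative labels — is not expressible in scipy's
  implementation; scipy's `linkage` serves as the independent oracle in
  tests. Average linkage is monotone, so merge heights never invert.
  Dendrograms export to Newick with half-height branch lengths, making
  leaf-to-leaf path length equal the merge height.

No tolerance below 1e−9 is asserted anywhere; all float comparisons in
tests carry explicit tolerances.

## qPCR quantification

Technical replicates are averaged per (gene, animal); `ΔCt = Ct_target −
Ct_ref` per animal; `ΔΔCt = ΔCt − mean(calibrator ΔCt)`; fold
`= 2^−mean(ΔΔCt)` over the test group — the fold of the group-mean ΔΔCt,
not the mean of per-animal folds, so the calibrator group's geometric-mean
fold is exactly 1. Amplification efficiency is fixed at perfect doubling
(no efficiencies are reported for the study). Significance is an unpaired
two-sided Student t on per-animal ΔCt (ΔCt, not folds, is the
approximately normal quantity); the reference gene self-normalises to
fold 1 with p = 1.

## Orchestration

YAML configuration with a versioned schema; unknown keys are errors
(pydantic `extra="forbid"`). Stages simulate → de → enrich → compare →
qpcr, each writing plain-text outputs re-readable by the package's own
parsers; a JSON manifest records the package version, config hash, seed
and a SHA-256 per file, so determinism is checkable by re-running. All
floats are serialised with a fixed `%.10g` format.

## Problem sizes

Calibration properties are established at the design scale the generators
define: 2,000-gene null studies and 1,000-gene planted studies (100 runs
each) for DE; 400 random-set runs at 199 permutations plus a planted-set
run at 999 for enrichment; 500 plate simulations for qPCR bias; 20 seeds
for block recovery; 1,000 random signature sets for the metric axioms.

## Known limitations

* The planted folds and noise levels are emulation choices, not fitted to
  the deposited data; absolute counts (e.g. "205 significant genes" in
  the demo) are properties of the demo configuration only.
* The moderated t assumes a common variance model across genes; with
  strongly heteroscedastic real arrays its prior-df estimate would shrink
  and results would approach the unmoderated tests.
* The enrichment NES scale depends on the gene-set permutation null and
  is not numerically comparable to phenotype-permutation NES values.
* `align_gene_panels` matches symbols case-insensitively but performs no
  ortholog or alias resolution.
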