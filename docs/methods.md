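# Methods

`phyloniche` implements a phylogenetic comparative analysis that asks whether
the size of particular gene-function categories predicts a species' climatic
niche breadth once phylogeny, primary genomic measures (genome size, total
genes, duplicated genes) and physiology (body mass, mass-specific metabolic
rate) are controlled for. This note records the models, the numerical
choices, and what the synthetic study does and does not emulate.

## Niche-breadth scores

**Climate envelope.** Per-cell values of the 19 bioclim variables across all
species' ranges are pooled and reduced with a single PCA, so every species
lives in one shared PC space. Each species' cells are projected onto
(PC1, PC2) and counted into an anisotropic occupancy grid; the envelope is
the number of occupied cells. Defaults:

- *PCA scaling*: covariance PCA (`scale=False`). The bioclim variables'
  raw variances are exactly what concentrates ~98% of variance on PC1 for
  real climate data; unit-variance scaling is available as a flag.
- *Grid*: `n1 = 981`, `n2 = 15` cells (14 715 total), i.e. ten times the
  typical percent variance contribution of each of the first two components;
  `EnvelopeGrid.from_contributions` computes `n_i = round(10 × contribution %)`
  if the data-driven variant is wanted. Grid bounds come from the pooled
  scores of **all** species so counts are comparable across species. Cells
  are half-open with the final row/column closed, so boundary points count
  once.
- *Occupancy reading*: the envelope is the count of **distinct occupied
  cells** (idempotent under duplicated points, monotone under added points).
  An alternative reading — total points falling in cells — would scale with
  sampling effort rather than niche breadth and is not a niche-breadth score.
- The envelope is square-root transformed before all regressions.

Raster extraction and range polygons are out of scope; the envelope consumes
pre-extracted per-cell climate tables.

**Brillouin habitat diversity.** For counts `n_i` of occupied cells per
climate class (e.g. Köppen–Geiger), `H = (ln N! − Σ ln n_i!)/N`, computed via
the log-gamma function. `H = 0` iff one class holds every cell, and for fixed
`N` and class count the most even partition maximizes `H` (tested
exhaustively for `N ≤ 12`).

## Genomic predictors

**Duplicated genes.** From an all-against-all protein homology search, a gene
is duplicated iff it participates — as query *or* subject — in at least one
same-species, non-self hit with `E < 1e-5` **and** query coverage `> 30 %`.
Both inequalities are strict, so hits exactly at a threshold never count.
Marking is symmetric (duplication is a pair property even though the search
is directional), one passing HSP suffices, and reciprocal hits are not
required. Coverage is alignment length ÷ query length × 100 when a query
length is supplied; otherwise an explicit coverage column is required, since
the standard 12-column tabular format carries neither.

**NOGF.** The number of genes per functional category is the count of
distinct genes annotated to the category in a flat gene → category map
(~384 categories in the synthetic catalogue). A gene in `k` categories
contributes once to each; categories outside the declared catalogue are an
error rather than being silently added.

## Comparative inference chain

1. **Contrasts.** Felsenstein's pruning algorithm converts the `n` tip
   values of every variable into `n − 1` standardized independent contrasts.
   Polytomies are a hard error (no silent zero-length resolution), as is a
   zero branch length in a contrast denominator — an epsilon substitution
   there would silently move every downstream statistic. Contrast order is
   deterministic postorder; signs follow child order in the input Newick
   (irrelevant to through-origin regression, but stable).
2. **LASSO screen.** Contrast regression has no intercept, so predictors are
   standardized by root-mean-square *without centering*. The penalty grid is
   100 log-spaced values from the null threshold (`max_j |X_jᵀy|/m`) down by
   1e-4. Mean squared prediction error is estimated by seeded k-fold CV
   (default 10 folds). `lasso_screen` defaults to the penalty minimizing
   mean CV error; the pipeline defaults to the **one-standard-error rule
   with the CV curve averaged over 5 repeated fold splits**. The 1-SE choice
   mirrors the default coefficient extraction of the standard R
   cross-validated LASSO tooling and keeps the screen sparse in the
   p ≫ n regime; the repeats stabilize the noisy CV curve that 31 contrasts
   produce, while the 1-SE band itself is still computed from fold-level
   spread (`sd/√folds`), keeping the rule conservative. The inner
   coordinate-descent solver is scikit-learn's; the reported solution
   satisfies the KKT stationarity conditions to 1e-6.
3. **PGLS.** For tip values `y ~ MVN(Xβ, σ²C)` with `C[i,j]` the shared
   root-path length of tips `i, j`, estimates are GLS via a Cholesky
   factorization of `C` (never an explicit inverse; a failed factorization
   surfaces as a not-positive-definite error). The likelihood is **ML with
   the profile variance** `σ̂² = rᵀC⁻¹r/n`, so AICc is comparable across
   models with different fixed effects; a REML toggle exists for
   single-model reporting. Standard errors carry the conventional
   `n/(n − k)` adjustment and p-values are two-sided t on `n − k` degrees of
   freedom (`k` = number of coefficients).
4. **Model set.** All `2^p` subsets of {screened categories + G, N_g, N_d,
   M, B_c}, intercept-only model included, guarded at `p ≤ 16`; the pipeline
   additionally caps screened categories at 11 (keeping the largest
   standardized coefficients) so the guard cannot trip mid-run.
   `AICc = −2 lnL + 2k' + 2k'(k'+1)/(n − k' − 1)` with `k'` counting
   coefficients plus the residual variance; models whose correction
   denominator is nonpositive are excluded with a warning. Ties in the
   minimum go to fewer parameters, then lexical predictor order.
5. **Averaging.** Akaike weights `w_i ∝ exp(−Δ_i/2)` over all fitted models;
   the confidence set is the smallest weight-ordered prefix with cumulative
   weight ≥ 0.95, with weights renormalized inside the set. The headline
   estimate is the full (zero-substitution) average; the conditional average
   (over models containing the term) is also reported, since averaging
   conventions differ between the two. Unconditional standard errors combine
   within-model variance and between-model spread,
   `√(Σ w'_i (se²_i + (β_i − β̄)²))`, and p-values are z-based because no
   single model supplies degrees of freedom.
6. **Gate.** A category's contribution stands only when its averaged p is
   **strictly** below 0.01.

The classical identity that the through-origin contrast slope equals the
Brownian PGLS slope is used as a cross-module oracle test (agreement to
1e-8 over random trees), and PGLS reduces exactly to OLS on a star
phylogeny.

Through-origin R² in correlation panels is `1 − RSS/Σy²` (no mean-centering);
conventions differ and this one is stated wherever reported.

## Synthetic study

The generator emulates a 32-species study with 384 gene-function categories:

- **Tree**: Yule (pure-birth) process, birth rate 1, pendant branches
  extended by a final exponential waiting time so all lengths are positive.
- **Predictors**: every category count and covariate evolves as an
  independent Brownian motion on the tree, exponentiated and rounded to a
  positive count where applicable; body mass spans grams to tonnes and
  metabolic rate follows a `M^(−1/4)` scaling with noise. Category base
  sizes are log-normal (median 20 genes) floored at 8 — smaller categories
  quantize to near-constant, spike-prone count vectors that no longer
  resemble a Brownian trait.
- **Signal**: `√envelope = 2 + 0.05 × (planted category count) + BM noise`
  with noise rate 0.42. These two numbers were calibrated once, by
  simulation on seeds disjoint from any evaluation seeds, so that the
  *pipeline-realized* contrast-level R² between the planted category and the
  square-root envelope has median ≈ 0.55 — a strong-but-not-overwhelming
  comparative signal.
- **Niche clouds**: all species share two orthonormal latent axes in
  19-dimensional climate space with variance split 98.1 : 1.5, so the pooled
  PCA reproduces the anisotropy of real bioclim data; within-species spread
  is proportional to latent breadth, making grid occupancy scale roughly
  with breadth² and hence `√occupancy` roughly proportional to breadth.
  1000 cells per species keep occupancy counts well above quantization
  noise.
- **Hits / maps**: homology tables contain the planted duplicate pairs plus
  decoys failing exactly one threshold (including exact-boundary decoys) and
  self hits; gene → category maps realize the category counts exactly, with
  adjacent categories sharing ~10 % of genes so multi-category membership is
  exercised.
- All generators are pure functions of (config, seed); one master seed fans
  out to per-component substreams so any stage can be regenerated
  independently and byte-identically.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: geography and spatial autocorrelation of
climate; correlation *between* functional categories (real functional
hierarchies share genes heavily across categories, real category counts all
scale with genome size); measurement error in body mass and metabolic rate;
non-Brownian trait evolution. The independence of the 383 decoy categories
matters statistically: with only 31 contrasts, the expected maximum spurious
correlation among 383 independent candidates is ≈ √(2 ln 383/31) ≈ 0.6, so
the variable screen occasionally admits a decoy whose post-selection
p-value then survives the 0.01 gate. In repeated synthetic runs the planted
category is screened in ~75 % of seeds and is the *sole* gated category in
~55–60 %; no individual decoy is accepted in more than ~4 % of runs. With
strongly inter-correlated categories (the realistic regime) the effective
number of independent decoys collapses and sole-category recovery is
markedly easier; emulating that correlation structure is deliberately out of
scope here.

## Degenerate inputs and tie-breaks

- An exactly collinear design raises an error naming the offending columns.
- A noiseless response (residual variance → 0) is flagged `degenerate`:
  coefficients are exact, standard errors are reported as 0 and the
  likelihood as +∞ rather than fabricating finite values.
- All-zero predictor columns are forced to coefficient 0 with a warning.
- Species present in some inputs but not others are dropped with a warning
  before analysis; fewer than 4 shared species is an error. Covariance for a
  subset of tips is the corresponding submatrix of the full Brownian matrix
  (the marginal of the multivariate normal), so no re-pruning arithmetic is
  involved in PGLS; contrasts do require pruning, which merges branch
  lengths through suppressed degree-2 nodes.

## Problem sizes used in validation

Simulation-based checks run at the study's native scale (32 species, 384
categories) with 50 seeds for end-to-end recovery, 100 seeds for screening
power at 50 noise categories, 500 replicates for slope recovery and
coverage, and 1000 replicates for null gate calibration; identity-style
checks (PIC↔PGLS, covariance oracle) use 100–200 random trees of 4–32 tips.
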