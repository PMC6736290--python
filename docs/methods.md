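# Methods

This note records the models, the numerical choices, and the places where
the design was genuinely open, in the package's own words. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and curation

The analyzed object is a species × toxin-family table of percent
abundances (a closed composition; rows sum to 100) with a per-species
categorical batch label (sequencing technology), plus a rooted,
time-calibrated, generally ultrametric phylogeny in My. Curation steps:

* **percent_normalize** — raw abundances (e.g. FPKM) to percent of the
  row total; zeros preserved; all-zero rows are an error.
* **prevalence_filter** — a family is kept iff it is present (abundance
  > 1e-6%) in at least 50% of species, boundary inclusive; retained rows
  are re-closed to 100 so downstream stages see a composition of the
  retained families.
* **impute_zeros** — deterministic simple multiplicative replacement:
  every zero cell receives δ = 0.65 × the smallest nonzero value of the
  table (overridable), nonzero cells are scaled by 1 − kδ/100 (k = zeros
  in the row). The literature's Bayesian-multiplicative routines need
  tuning parameters the analysis does not pin down; the deterministic
  variant is reproducible and testable, and the choice is recorded in the
  run report.
* **clr_transform** — scikit-bio's centered log-ratio; requires strictly
  positive input, so it always follows imputation.

## The phylogenetic mixed model

Multivariate animal model with the phylogeny as pedigree: for n species
and m families, y = Xβ + a + e with a ~ N(0, G ⊗ A), e ~ N(0, R ⊗ I).

* **A matrix.** Shared root-to-MRCA path lengths; divided by tree height
  by default so an ultrametric tree has unit diagonal. This keeps G and R
  on one scale and makes λ = G_ii/(G_ii+R_ii) interpretable on [0, 1]
  (Pagel's-λ analog). The unscaled matrix is available (`scale_vcv`).
* **Response scaling.** Each retained family is centered and scaled to
  unit variance across species before fitting (flag `response_scaling`),
  so PCOV entries and λ are comparable across families; the clr refit
  uses the same scaling.
* **Fixed effects.** Intercept per family plus batch contrasts
  (first-level reference coding).
* **Priors.** Inverse-Wishart on G and R, scale I, ν = m + 1 — proper and
  weakly informative; ν can be lowered toward m (e.g. m + 0.002) through
  `prior_df` for a near-flat prior.
* **Sampler.** Exact blocked Gibbs in the eigenbasis of A (A = QΛQ′). Per
  sweep: β is drawn from its marginal Gaussian posterior (integrating the
  phylogenetic effects analytically, per-species covariance λⱼG + R),
  then u | β from its Gaussian conditional, then G and R from conjugate
  inverse-Wishart full conditionals (Bartlett construction). Drawing β
  from the marginal and then u | β is exactly the joint (β, u) block
  update; the eigenbasis makes each sweep O(n m³). Deviance −2 log p(y |
  β, u, R) is stored per kept draw.
* **Chain settings.** Default 50,000 sweeps, 10,000 burn-in, thinning 20
  (2,000 stored draws) — sized so the full pipeline runs in minutes while
  keeping Monte-Carlo error well below posterior spread; the original
  study's 20M/1M/1,500 settings are recorded as the `paper()` preset.
* **Summaries.** Entrywise posterior means; 95% HPD as the shortest
  empirical interval; an off-diagonal G entry is "significant" when its
  HPD excludes 0 (diagonal never flagged; no multiple-testing correction,
  matching the study design and flagged in the report). λ is "significant"
  when its HPD lower bound exceeds 0.05 — λ is positive by construction,
  so "greater than zero" needs an operational floor; 0.05 is recorded in
  the report.
* **Diagnostics.** ESS = n/(1 + 2Σρ_k) with Geyer's initial-positive-pair
  truncation; lag autocorrelations; DIC = 2·mean(D) − D(posterior means)
  for the raw-vs-clr fit comparison (the analysis names no criterion for
  "worse fit"; DIC is the natural choice for this sampler).

## Phylomorphospace

PCA is performed on the posterior-mean PCOV itself, not on the raw data
covariance — the axes describe *heritable* covariation. Eigenvalues are
sorted descending; each axis is signed so its largest-magnitude loading
is positive (a deterministic convention for reproducible plots and
tests). Species scores project the scaled abundances, centered on the
arithmetic cross-species mean, onto the eigenvectors; the
phylogenetically weighted (GLS) mean is available via a flag since the
original choice is unstated.

## Stepwise OU convergence search

Hansen model: per trait one α ≥ 0 (1/My) and σ² > 0 shared across
regimes, one optimum θ per regime. Tip covariance
V = σ²/(2α)·e^{−α d}(1 − e^{−2α s}); the Brownian limit σ²·s is evaluated
directly when αT < 1e-8. Optimum weights follow the path-segment formula
with e^{−αT} absorbed into the basal column (no separate root-state
parameter). Fitting profiles θ (GLS) and σ² analytically and optimizes
log α by bounded scalar search on [1e-6/T, 100/T] (xatol 0.01); the
parameter count is p = m(2 + k′) and model scores use AICc (plain AIC via
flag), n = number of species.

Forward phase: evaluate a brand-new regime on every branch that is not
already a shift point (shifts are placed at the rootward end of a branch
and inherited until overridden), accept the best placement if it improves
the score by more than the threshold (default 0), repeat; candidates are
visited in preorder so ties resolve deterministically. Backward phase:
evaluate every pairwise regime merge, accept the best improvement,
repeat; final regimes are renumbered contiguously.

Metrics: k = 1 + #shifts, k′ = distinct regimes, Δk = k − k′, c = number
of placements whose regime is reached by ≥ 2 placements — the basal
placement counts, so a reversion to a shared basal regime is convergent
with it (flagged in the run report, as the convention is not pinned down
elsewhere).

**Null distribution.** Each iteration simulates traits under the
forward-phase fit with every shift in its own regime *and a freshly drawn
optimum* (Normal with the mean and spread of the fitted optima), then
re-runs the full forward+backward search. Cloning the fitted optima
verbatim would reproduce the convergent optima under different labels and
the backward phase would rightly re-merge them — the resampling is what
makes "no true convergence" real. P-values use the add-one convention,
(#{null ≥ obs} + 1)/(n + 1), reported to 3 decimals, never exactly 0.

**Known limitation.** Greedy shift addition under AICc is anticonservative
by construction: the best of ~2n candidate placements on shift-free data
has max ΔlnL ≈ ln(2n) plus noise, which exceeds the ΔAICc ≈ 2m + ε hurdle
for small m. On pure single-regime data the search therefore accepts
spurious shifts, some of which later merge (measured mean Δk ≈ 1.8 on
50-tip, 2-trait data). This is a property of the stepwise-AIC method
family itself, inherited deliberately; the simulated null exists
precisely to calibrate the observed c and Δk against this behavior, and
the acceptance suite reports the effect rather than masking it.

## Ancestral reconstruction

Per family, independently (matching the study design): Brownian motion
with rate σ̂² = Σ(standardized contrasts²)/(n−1), contrasts formed by
folding children sequentially so polytomies are handled. Estimates come
from two-pass Gaussian message passing — upward (pruning) then downward —
which yields at every internal node the re-rooted ML value, identical to
the GLS conditional expectation with the GLS root mean (verified against
dense matrix inversion at 1e-8). Variance = σ̂² × the node's combined
message variance; on an equal-branch star tree the root variance factor
is exactly 1/n. CIs use ±1.96σ (the CI level is unstated in the source
analysis; 95% matches the package's other intervals). Zero-length cherry
branches are guarded with an ε of 1e-12 × tree height. Negative
reconstructed abundances are reported as-is; the presence rule (CI lower
bound > 0) handles interpretation.

## Synthetic data generator

The generator defines the study conditions for all tests:

* **Tree.** Yule process (exact exponential waiting times, uniform
  lineage choice), rescaled to height 60 My, 52 tips by default.
* **Latent abundances.** Multivariate BM + residual noise on the log
  scale: G = diag(λᵢ·vᵢ), R = diag((1−λᵢ)·vᵢ) with λ = 0.8 for the four
  major families (TFTx, SVMP, PLA2, SVSP) and 0.5 for the rest. Latent
  means descend from 1.0 (majors) to −1.05 (rarest retained family);
  total variances are 1.0/0.9 (majors) and 0.5 (minors). The variances
  are deliberately moderate: large major-family swings would dominate
  the softmax denominator and manufacture strong closure covariances
  among the minor families, a regime the study's percent-scale covariance
  matrix (almost no significant entries) does not show.
* **Composition.** Softmax of the latent values × 100; a cell more than
  4.5 natural-log units below its row maximum (≈ below 1% abundance) is a
  structural zero — a detection-limit rule, so zero placement is explicit
  and closure is exact.
* **Decoys and batches.** 15 decoy families present in ~20% of species at
  low levels (exercising the prevalence filter), and 3 technology batches
  assigned independently of the phylogeny with additive latent shifts
  (SD 0.3), so batch-invariance of the PCOV is testable.
* **What it does not emulate.** Read-level noise, within-species venom
  variation, correlated (non-diagonal) true G, non-random study/species
  selection, and tree uncertainty. Passing tests therefore show the
  pipeline recovers known structure of this generative class, not that
  the biological conclusions of any particular dataset are correct.

## Scaled-down test conditions

Recovery tests run at sizes chosen for desk-scale runtimes: 50-tip trees
and 50k-sweep chains for G (m = 5; averaged over 5 seeds against a 0.35
Frobenius tolerance — per-seed error is dominated by genuine posterior
spread, since the height-scaled Yule VCV carries roughly half its nominal
observations' worth of information about G) and for λ (m = 3, ±0.15);
100-tip trees for single-regime Hansen recovery; 20 planted-convergence
and 50 shift-free seeds for the search's power and size; 100 null
simulations in the acceptance pipeline (500 in the `paper` preset).
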