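# Methods

## Diversity partitioning

All diversity quantities derive from Rao's quadratic entropy
Q(p, d) = Σᵢⱼ dᵢⱼ pᵢ pⱼ, the expected dissimilarity between two
individuals drawn with replacement. The taxonomic facet (TD) uses unit
dissimilarities (Q then equals Gini–Simpson, 1 − Σpᵢ²); the
phylogenetic facet (PD) uses patristic distances, i.e. summed branch
lengths between tips. When a posterior sample of trees is supplied,
per-tree patristic matrices are averaged element-wise into a single
mean distance matrix used throughout (pruning before or after distance
computation is equivalent for patristic distances, so trees are pruned
first).

Two magnitude corrections are implemented as independent flags, both
on by default through `corrected=True`:

1. **Equivalent numbers** — dissimilarities are rescaled to [0, 1] by
   the regional maximum and Q is transformed to 1/(1−Q), the number of
   equally abundant, maximally distinct species with the same entropy.
2. **Two-community β maximum** — the proportional pairwise β,
   (γ_pair − ᾱ)/γ_pair, computed from equivalent numbers, is divided
   by its theoretical maximum for N = 2 communities (1 − 1/N = ½, i.e.
   multiplied by 2) before the ×100 scaling.

The published corrections this mirrors are cited but not printed in
the source study, so their exact combination is not recoverable; both
flags are recorded in outputs. Note a practical caveat found during
calibration: the equivalent-number transform amplifies richness
differences, which in gradient-association tests (Mantel) can swamp or
even invert the compositional turnover signal. For association tests
the raw multiplicative β is the more reliable statistic, and the
acceptance checks use it; the corrected values remain the default for
reporting magnitudes.

Pooling for γ_pair sums raw counts and renormalizes (plots weighted by
sampling effort); `pooling="equal"` averages relative-abundance
vectors instead. β ∈ [0, 100] is guaranteed for unit and ultrametric
(patristic) dissimilarities, for which Rao entropy is concave in p; it
can fail for arbitrary non-metric dissimilarity inputs.

## Null model and SES

The null shuffles taxon labels across the tips of the regional
phylogeny — implemented as co-permutation of the regional distance
matrix — leaving abundances, per-plot richness and the distance
multiset intact. Defaults: 3000 permutations for α/β-PD, 999 for the
MPD robustness variant, α = 0.025 per tail. The standard deviation in
SES uses n−1. Ties count toward the extreme tail and the observed
value is not added to the null set. One permutation stream is shared
across all species groups per iteration so cross-group comparisons see
a common null (`shared_shuffle=False` gives independent streams; the
choice is recorded in the output). A numerically zero null spread
(monospecific plots, identical compositions) yields SES = NaN and
classification "undefined".

For the regional pool, the plant groups (all life stages) share one
pooled phylogeny; birds use their own tree. With unit dissimilarities
the null is exactly degenerate (entropy depends only on abundances),
which is why SES is a PD-only diagnostic.

## Environmental axes

The 15 plot variables (fragment size, edge length, perimeter/area,
seven vertical biomass layers, canopy cover, relative light, Shannon
heterogeneity of the biomass profile, and two binary habitat dummies)
enter a PCA on the correlation matrix; dummies are ordinary 0/1
columns. Components are ordered by eigenvalue with a deterministic
sign convention (largest-magnitude loading positive); PC1 is then
flipped so the canopy-cover loading is negative ("disturbance" = more
open canopy) and PC2 so the fragment-size loading is negative ("loss"
= smaller fragments). Broken-stick proportions
bₖ = (1/n) Σᵢ₌ₖⁿ 1/i give an advisory retention count; the regression
stage always uses exactly the two named axes because the model
formulas require them.

## α-diversity models

Responses are corrected Rao α-TD and α-PD SES per plot. Plants use a
linear mixed model with plot random intercept over the stacked life
stages (terms: life stage, disturbance, their interaction, loss,
easting, northing); birds use OLS with the four continuous predictors.
All continuous predictors are Z-scored (sample SD). Fits are maximum
likelihood, never REML, so AICc values are comparable; k counts fixed
effects plus the residual variance plus (when present) the
random-intercept variance; AICc = 2k − 2ℓ + 2k(k+1)/(n−k−1).

Dredging enumerates every subset of the fixed terms respecting
marginality (an interaction requires both parents), including the
intercept-only model. When the random-intercept variance collapses to
the boundary the ML Hessian is singular in `statsmodels`; such members
are refitted as the boundary model (OLS estimates, which coincide with
the ML fit at variance 0) with the variance component still counted in
k, rather than dropped — this keeps dredge sets complete and mirrors
how lme4 reports singular fits. Genuine failures are dropped with a
warning.

Averaging uses Akaike weights wₘ ∝ exp(−Δₘ/2) over the ΔAICc < 2 set.
Conditional (subset) averaging is the default; full-model
(zero-substitution) averaging is available. Unconditional SE follows
Burnham–Anderson, √(Σ wₘ (seₘ² + (θₘ − θ̄)²)); the "adjusted" SE
additionally inflates each within-model variance by dfₘ/(dfₘ−2) with
dfₘ = n − (fixed effects), a small-sample correction chosen here
because the source study's exact adjustment is not printed. z =
estimate/adjusted SE with two-sided normal p; a term's importance is
its summed weight over retained models containing it.

## β-diversity, space and variation partitioning

Gradient distance matrices are |Δ| of the plot scores; geographic
distances are Euclidean in metres. The Mantel statistic is the Pearson
correlation of lower triangles; significance permutes the rows and
columns of the first matrix (999 permutations by default, one-tailed
"greater", p = (extreme + 1)/(n_perm + 1)). The partial Mantel
statistic is the first-order partial correlation
(r_AB − r_AC r_BC)/√((1−r_AC²)(1−r_BC²)) with A permuted and B, C
fixed; |r_BC| = 1 is refused as degenerate conditioning.

PCNM eigenvectors come from a PCoA of the geographic distance matrix
truncated at the longest minimum-spanning-tree edge (larger entries
replaced by 4× the threshold); positive-eigenvalue eigenvectors are
kept, unit-norm, eigenvalue-ordered. Forward selection on an RDA uses
the double stop at α = 0.050: a candidate (the one adding most
explained variance) must pass a residual-permutation test, and
selection stops once the adjusted R² of the *already-selected* model
reaches the full-candidate model's adjusted R². The ceiling is
deliberately applied to the selected model, not the candidate model:
with few plots and uninformative candidates the expected adjusted R²
of the full model lies at or below that of the true predictor subset,
so a candidate-model ceiling (as in some R implementations)
systematically rejects the last genuine predictor. The full-model
significance gate runs first and an empty selection is a valid
outcome.

Because β matrices are dissimilarities, RDA runs on their
principal-coordinate embedding (db-RDA); negative eigenvalues are
handled by the Lingoes constant correction by default (square-root and
drop options available). β-PD SES matrices can be negative, so they
are shifted by their minimum off-diagonal value before embedding.
R² is the explained inertia fraction, adjusted by Ezekiel's
1 − (1−R²)(n−1)/(n−p−1). Variation partitioning fits the seven
marginal db-RDA models over {disturbance, loss, selected spatial
eigenvectors}, converts to adjusted R², and solves the Venn fractions
by inclusion–exclusion; adjusted fractions may be slightly negative
(reported as-is). Unique fractions are tested by permuting residuals
under the conditioning sets. An empty predictor set (e.g. no selected
spatial eigenvectors) contributes zero fractions and is noted.

## Posterior sweep

`pipeline.posterior_sweep` repeats the α-PD SES → dredge → average
chain and the β-PD partial Mantel test per tree of a posterior sample,
reporting per-tree statistics, their means/SDs, and how often each
predictor entered the averaged model. Member failures are tallied, not
fatal. Defaults are scaled per call; the test and acceptance runs use
small sweeps (≤ 10 trees, a few hundred permutations), which is ample
to verify the zero-jitter degenerate case and mean-matrix consistency.

## Synthetic data generator

The generator emulates the study design the analysis assumes: 30 plots
in 5 forest-modification classes split across two spatially clustered
reserves; 166 plant species observed as adults (≈72 individuals per
plot), saplings (≈23) and seedlings (≈27); 85 bird species (≈27
individuals per plot) on an independent tree; a dominant latent
"disturbance" gradient aligned with the modification classes and a
weaker, independent "loss" gradient; 15 observed environment variables
responding linearly (disturbance opens the canopy, raises low-layer
biomass and light, flips forest type; loss shrinks fragments and flips
the matrix dummy), with heterogeneity computed from the generated
biomass profile itself.

Phylogenies are birth–death trees conditioned on the tip count
(defaults b = 1.0, d = 0.5, ultrametric). Species carry a Brownian
trait syndrome simulated along the tree. Three generator choices
deserve emphasis because they are what make the premise "relatedness
implies ecological similarity" hold reliably per realization rather
than only on average:

* the syndrome is multivariate (3 traits by default) — a single trait
  decouples from the phylogeny by convergence too often;
* the trait rate follows an early-burst decay, exp(−a·t/depth) with
  a = 3 by default (`early_burst=0` recovers plain Brownian motion) —
  conditioned birth–death trees are frequently near-star-shaped, and
  concentrating divergence on deep branches makes clades separate in
  trait space regardless of tree shape;
* the plot trait optimum travels along the syndrome's leading
  principal axis — the direction shaped by the deepest splits — so the
  filtered trait band maps onto clades.

Communities assemble per plot and group with sampling weight
exp(−λ·z²), z² the mean squared standardized trait distance to the
plot optimum, and λ = filter_strength(group) + disturbance_effect ×
disturbance, floored at 0 for filtering baselines (disturbance
modulates strength; it cannot flip the assembly mode). An explicitly
negative filter_strength switches the group to repulsion: sequential
species choice penalizing trait similarity to already-chosen species
(limiting similarity). Abundances are multinomial at the configured
per-plot effort.

Named scenarios: `neutral_config` (all λ = 0 — used for type-I
calibration) and `strong_filtering_config` (low baselines, steep
disturbance effect: adults 0.3, saplings 0.8, seedlings 1.0, slope
1.5, optimum shift 1 SD — the strong-signal regime for power checks;
low baselines matter because high ones saturate the SES along the
whole gradient and flatten the slope).

**What the generator does not emulate:** real demographic links
between life stages (stages are assembled independently given the
gradient), dispersal limitation beyond coordinate clustering,
abundance structure beyond multinomial sampling, detection error, and
trait evolution beyond (early-burst) Brownian motion. Passing
calibration and power checks on these data therefore demonstrates that
the statistical machinery is correct and calibrated, not that any
particular field system behaves this way.

## Numerical choices and degenerate inputs

* Distance matrices are emitted with lexicographically sorted labels;
  trees with any missing branch length are rejected rather than
  silently zero-filled; zero-length terminal branches are allowed.
* Null spreads below 10⁻¹² (relative) are treated as exactly zero
  (undefined SES) to keep degenerate cases from masquerading as huge
  effect sizes.
* PCA signs are deterministic (largest-magnitude loading positive,
  then the canopy/size orientation flips described above).
* All permutation procedures draw from `numpy` Generators seeded from
  a single master seed; identical seeds reproduce results bit-for-bit
  in single-threaded execution.
* Mixed-model optimizers are tried in sequence (lbfgs, powell, cg,
  nm) before declaring a boundary fit.
* Analysis sizes used in the shipped tests and acceptance script (500
  null permutations, 199–999 Mantel permutations, 25–200 replicate
  datasets, posterior sweeps of ≤ 10 trees) were chosen as the
  smallest runs that hold Monte-Carlo error comfortably below the
  tolerances being checked.

## Known limitations

* The mixed model supports a single random intercept (the plot); no
  crossed or nested random effects.
* Conditional model averaging reports conditional (not shrunken)
  estimates; importance weights are summed Akaike weights, with the
  usual caveats about correlated predictors.
* db-RDA on shifted SES matrices is a pragmatic device; the shift
  preserves ordering but the embedding is not unique.
* The exact correction stack of the source framework for corrected
  Rao values is ambiguous (see Diversity partitioning); magnitude
  comparisons across studies should state both flags.
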