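# phylorao

Taxonomic and phylogenetic α- and β-diversity partitioning for
communities sampled along landscape-modification gradients — Rao
quadratic-entropy diversity, tip-shuffle null models with standardized
effect sizes, environmental PCA, AICc multimodel inference, partial
Mantel tests, PCNM spatial eigenvectors and variation partitioning,
plus a synthetic-landscape generator so the whole pipeline can be
exercised and calibrated without field data.

## Who this is for

Community ecologists and community phylogeneticists who have

* one or more phylogenies (Newick; single trees or posterior samples),
* plot × species abundance tables for one or more species groups
  (e.g. successive tree life stages, birds), and
* a plot-level table of habitat characteristics with coordinates,

and who want to ask whether habitat modification filters communities
phylogenetically (underdispersion), whether competition spreads them
out (overdispersion), and how much of the compositional turnover
between plots is explained by environmental gradients versus space.

## The model

**Diversity.** Rao's quadratic entropy is the expected dissimilarity
between two randomly drawn individuals,

    Q(p, d) = Σᵢ Σⱼ dᵢⱼ pᵢ pⱼ,

with relative abundances *p* and species dissimilarities *d* — unit
dissimilarities give the taxonomic facet (TD, reducing Q to the
Gini–Simpson index), patristic tree distances give the phylogenetic
facet (PD). Corrected values are expressed as equivalent numbers
1/(1−Q) after rescaling *d* to [0, 1]. Pairwise β-diversity is
partitioned multiplicatively,

    β = (γ_pair − ᾱ) / γ_pair × 100,

where γ_pair is the Rao entropy of the pooled plot pair and ᾱ the mean
of the two plot entropies.

**Null model.** Observed PD values are standardized against a null that
shuffles taxon labels across the tips of the *regional* phylogeny
(equivalently, co-permutes the rows and columns of the regional
distance matrix), preserving abundances, richness, and the distance
multiset:

    SES = (OBS − mean(EXP)) / sd(EXP).

Plots (or plot pairs) are classified overdispersed / underdispersed
when the observed value falls outside the central 1 − 2α of the null
(α = 0.025 per tail by default); a zero null spread (e.g. a
monospecific plot) yields an undefined SES, never a crash.

**Inference.** Environmental gradients come from a PCA on the
correlation matrix of the plot characteristics (PC1 = "forest
disturbance", PC2 = "forest loss", with broken-stick retention
advisory). α-diversity responses are modelled by maximum likelihood —
a linear mixed model with plot random intercept across plant life
stages, an ordinary regression for birds — dredged over all
marginality-respecting predictor subsets, and averaged over the
ΔAICc < 2 set with Akaike weights. β-diversity is related to gradient
distances by partial Mantel tests conditioned on geographic distance,
and decomposed by db-RDA variation partitioning over disturbance, loss
and forward-selected PCNM spatial eigenvectors.

## Worked example

```python
import warnings
from phylorao import pipeline
from phylorao.synthetic_data import strong_filtering_config, simulate_dataset

config = strong_filtering_config(seed=7)   # 30 plots, 166 plant + 85 bird species
bundle = simulate_dataset(config)
result = pipeline.run_alpha(bundle, n_perm=1000, seed=7)
print(result["reports"]["plant_pd"].table.round(3))
print(result["dispersion"])
```

prints the averaged-model report for plant α-PD (SES):

```
                                       estimate     se  ...       z      p
coefficient                                             ...
Intercept                                -3.396  0.266  ... -12.597  0.000
C(life_stage)[T.sapling]                  1.151  0.264  ...   4.303  0.000
C(life_stage)[T.seedling]                 0.427  0.264  ...   1.598  0.110
disturbance                              -3.142  0.271  ... -11.456  0.000
C(life_stage)[T.sapling]:disturbance      0.786  0.269  ...   2.889  0.004
C(life_stage)[T.seedling]:disturbance     1.217  0.269  ...   4.474  0.000
northing                                 -0.253  0.220  ...  -1.136  0.256
easting                                  -0.221  0.221  ...  -0.990  0.322
```

and the dispersion tally:

```
classification  overdispersed  underdispersed  random  undefined
group
adult                       1              15      14          0
bird                        0              13      17          0
sapling                     1              15      14          0
seedling                    0              15      15          0
```

Read: this strong-filtering scenario assembles communities by
trait-based environmental filtering that intensifies with disturbance,
so plant α-PD declines steeply along the disturbance axis (estimate
−3.14 in SES units per SD of disturbance, p < 0.001), the decline is
weaker for saplings and seedlings relative to adults here only because
their baseline filtering is already strong (positive interactions), and
roughly half the plots are flagged as significantly underdispersed.
The `seed` makes every permutation and simulation reproducible.

A command-line interface wraps the same pipeline:

```sh
phylorao simulate --seed 7 --out bundle/
phylorao alpha --bundle bundle/ --seed 7 --out reports/
phylorao beta  --bundle bundle/ --seed 7 --out reports/
```

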