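# phylorange

Phylogenetic comparative analysis of species geographic range size against
ecological niche breadth and dispersal ability.

A recurring question in macroecology is why some species occupy continents
while close relatives are confined to single mountain ranges. Two candidate
explanations dominate: broad ecological niches (climatic tolerance, diet
breadth, habitat flexibility) let species find suitable conditions over
larger areas, and strong dispersal lets them reach those areas. Comparing
the two requires per-species niche and dispersal metrics and a regression
framework that accounts for the non-independence of related species.
`phylorange` implements that full workflow for assemblages such as the
European butterflies: predictor construction, phylogenetic regression,
variance decomposition, and a local-regression map of how effects vary
across the tree — plus a synthetic-data generator so every stage can be
exercised and validated with known ground truth.

## What it computes

**Predictors** (one value per species):

- *Climate niche breadth*: occurrence records are cleaned (duplicates,
  zero coordinates, uncertainty > 10 km, records before 1980), snapped to
  grid cells of a bioclimatic raster table, projected onto the first four
  principal components of the 19 bioclimatic variables (PCA fitted on
  10,000 random cells), and the occupied score cloud is enclosed by a
  one-class SVM whose volume is estimated by Monte-Carlo sampling.
  Optionally the number of cells per species is capped (e.g. at 50, with
  10 random replicates) to control sampling-effort bias; species with
  fewer than five occupied cells receive the minimum volume computed among
  the remaining species.
- *Diet niche breadth*: Faith's phylogenetic diversity (total branch length
  of the minimal root-connected subtree) of the species' host-plant genera
  on a host genus tree.
- *Habitat niche breadth*: count of broad reproductive habitat types used
  (out of seven: wetlands, sparsely vegetated land, grasslands, shrubland,
  forest, mixed cultivated land, arable land).
- *Wingspan*: geometric mean of min/max per source, averaged across
  sources, preferring female-specific measurements.
- *Dispersal tendency*: ordinal class 1..3 (sedentary / moderately mobile /
  dispersive), mapped from nine-level expert scores.

**Model.** With y = log range size (km²) and x the square-root-transformed,
standardized continuous predictors plus the raw ordinal dispersal class,
the package fits the generalized least squares model

    y = Xβ + ε,   ε ~ N(0, σ²R)

by maximum likelihood, where R comes from the phylogeny: under Brownian
motion R_ij is the shared root-to-ancestor path length V_ij; under the
Ornstein–Uhlenbeck (Martins–Hansen) structure R_ij = exp(−α d_ij) with
d_ij the patristic distance and α profiled by a bounded scalar search.
The two structures are compared with a likelihood-ratio test. Predictor
importance is measured by the predictive pseudo-R²

    R²_pred = 1 − Var(y − ŷ_full) / Var(y − ŷ_reduced)

where ŷ are leave-one-out conditional expectations under the fitted
phylogenetic covariance; reduced models drop one predictor with α held at
the full-model estimate, a full OLS fit isolates the phylogeny's share, and
the intercept-only null gives the total. Capped-replicate fits are
summarized with equal-weight model averaging (estimates averaged; SEs via
the unconditional-variance formula √(SE_i² + (est_i − mean)²), averaged).

**Non-stationarity.** A multivariate phylogenetically weighted regression
fits one weighted regression per focal species with weights
w_ij = exp(−b d_ij), bandwidth b optimized by leave-focal-out squared
prediction error; each focal coefficient is classified positive / negative /
non-significant from its 95% confidence interval (t quantile on the
effective sample size (Σw)²/Σw² minus the parameter count).

## Worked example

```python
from phylorange import SimulationConfig, simulate_range_dataset
from phylorange.design import prepare_design
from phylorange.gls import coefficient_table, fit_pgls_ml, likelihood_ratio_test, partial_r2_table

dataset = simulate_range_dataset(SimulationConfig(seed=7))   # 369 species
dm = prepare_design(dataset.traits)
fit_bm = fit_pgls_ml(dm.y, dm.X, dataset.tree, model="BM")
fit_ou = fit_pgls_ml(dm.y, dm.X, dataset.tree, model="OU")
print(coefficient_table(fit_ou).round(3))
print(likelihood_ratio_test(fit_bm, fit_ou))
print(partial_r2_table(dataset.traits, dataset.tree).round(3))
```

prints (abridged):

```
                       estimate     se       t      p
Climate niche breadth     1.537  0.092  16.642  0.000
Diet niche breadth        0.058  0.091   0.642  0.521
Habitat niche breadth     0.182  0.090   2.022  0.044
Wingspan                 -0.070  0.094  -0.743  0.458
Dispersal tendency       -0.095  0.108  -0.887  0.376

{'chi2': 149.3, 'df': 1, 'p': 2.5e-34}

                          r2
Full model             0.620
Climate niche breadth  0.403
...
Phylogeny              0.177
```

The climate coefficient recovers the generating value (1.56) within its
standard error, the zero-effect predictors stay near zero, the large LRT
statistic correctly prefers the OU residual structure the data were
generated under, and the variance decomposition attributes the bulk of the
explained variance to climate niche breadth with a separate share for the
phylogeny itself. The scripts in `examples/` walk through each capability
(simulation, PGLS, variance decomposition, weighted regression, raw niche
metrics) with commentary.

A thin CLI wraps the pipeline: `phylorange simulate`, `phylorange pgls`,
`phylorange pwr`, `phylorange run --config config.yaml`; outputs are
bit-stable TSV/JSON files plus a run log.

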