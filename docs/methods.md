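# Methods

This note documents the statistical procedures implemented in `phylorange`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## The comparative model

The response is the natural logarithm of range size in km². The four
continuous predictors (climate, diet and habitat niche breadth, wingspan)
are square-root transformed and standardized to zero mean and unit SD; the
ordinal dispersal class enters as a raw numeric 1..3 column. The log base
and the unstandardized ordinal are deliberate: coefficients of standardized
predictors are directly comparable to each other, while the ordinal
coefficient is per-class-step. Collinearity is screened before fitting with
Pearson r (continuous pairs) and Spearman ρ (pairs involving the ordinal),
flagged inclusively at |coefficient| ≥ 0.7.

GLS estimation is maximum likelihood throughout, never REML: the point of
fitting both residual structures is the likelihood-ratio test between them,
which is only valid on comparable ML log-likelihoods. The residual
structure is either the Brownian-motion covariance (V_ij = shared
root-to-MRCA path length) or the Ornstein–Uhlenbeck correlation
R_ij = exp(−α d_ij) on patristic distances; both are defined up to a scale
that the ML residual variance absorbs, so the log-likelihood is invariant
to that normalization. α is profiled with a bounded Brent search on
[1e−6/H, 50/H] (H = root height; relative tolerance 1e−8), and a fit whose
optimum lands at either bracket carries a boundary warning. Reported
standard errors apply the n/(n−p) ML-to-unbiased variance adjustment and t
statistics use n − p degrees of freedom — the convention of standard GLS
summaries, adopted because the ML/df question is otherwise undecidable
from coefficients alone.

Trees are rescaled to unit root height before analysis. α and the PWR
bandwidth are rates per unit branch length, so fixing the height makes
their values comparable across trees of different depth and keeps the
profile bracket meaningful for any input tree.

## Predictive pseudo-R² and the drop-one ladder

Predictor importance uses the predictive pseudo-R²,
1 − Var(y − ŷ_full)/Var(y − ŷ_reduced), where each fit's prediction for
species i is the leave-one-out conditional expectation
x_iβ̂ + Σ_{i,−i}Σ_{−i,−i}^{-1}(y − Xβ̂)_{−i} under the fitted covariance
Σ = σ²R. Internally this is computed with the equivalent closed form
(R⁻¹e)_i/(R⁻¹)_ii; the brute-force submatrix formula is kept as an
independent oracle in the test suite. Reduced models in the drop-one
ladder re-use the full model's α verbatim rather than re-estimating it, so
the comparison isolates the predictor's contribution; the phylogeny's
share compares the full phylogenetic fit with a full OLS fit, and the
total compares it with the intercept-only null (prediction = ȳ). Reported
tables floor values at zero; raw (possibly slightly negative) values are
retained alongside.

In constrained mode the whole ladder runs once per capped climate-breadth
replicate, each replicate estimating its own full-model α, and the table
reports mean (min–max). Replicate coefficient fits are combined by
equal-weight model averaging: the estimate is the mean and the SE is the
mean of √(SE_i² + (est_i − mean)²), which folds between-replicate spread
into the reported uncertainty; p-values use t statistics on these averaged
quantities.

## Phylogenetically weighted regression

One weighted least-squares fit per focal species with weights
exp(−b d_ij), w_ii = 1 (zero patristic distances are allowed and receive
full weight). Standard errors use the weighted residual variance on the
effective sample size n_eff = (Σw)²/Σw²; confidence intervals use
t_{0.975, n_eff − p}. A focal species with n_eff ≤ p is flagged failed
(NaN row) rather than aborting the whole analysis. Classification is
purely interval-based: positive if the CI lower bound exceeds zero,
negative if the upper bound is below zero, otherwise non-significant. No
multiplicity correction is applied anywhere; outputs are raw intervals and
counts.

The bandwidth criterion is a design choice: b minimizes the total
leave-focal-out squared prediction error (each focal's own observation
removed from its fit), searched by Nelder–Mead on log b from multistarts
{0.1/H, 1/H, 10/H} with the global-regression limit b = 0 also scored.
A simplex-style derivative-free search is used because the objective is
cheap but not smooth in closed form; the leave-focal-out criterion was
chosen because it directly penalizes both over-localization (tiny n_eff,
noisy fits) and under-localization (ignoring real non-stationarity).

## Hypervolume estimation

Climate niche breadth encloses a species' occupied 4-D PCA score cloud
with a one-class SVM (Gaussian kernel) and estimates the enclosed volume
by uniform Monte-Carlo sampling of the bounding box expanded by one kernel
lengthscale per side. Two numerical choices matter:

- **Kernel width is adaptive.** The lengthscale is set to twice the mean
  point spacing (bbox_volume/n)^(1/4), i.e. γ = 1/(2ℓ²), with ν = 0.05.
  A fixed γ cannot be right at more than one data scale: the decision
  boundary bulges beyond the data by a margin proportional to the kernel
  lengthscale, so a width tuned for a unit cloud over-estimates small
  clouds and erodes large ones. With the adaptive width, recovery of known
  box volumes {1, 2, 16} from 5000 uniform points is within a few per
  cent, and the estimator is automatically scale-equivariant (scaling all
  axes by c scales the volume by c⁴). The small ν erosion balances the
  residual outward bulge.
- **Monte-Carlo budget is fixed** at 100,000 samples per estimate with a
  recorded seed. Because the expanded box is tied to the data spread, the
  inside-fraction — hence the relative MC error, about 0.6% for compact
  clouds — is roughly scale-invariant, so a fixed budget gives uniform
  precision.

PCA variables are scaled to unit variance before the eigendecomposition
(the 19 bioclimatic variables mix units); loading signs follow the
largest-magnitude-entry-positive convention. Occurrences map to cells by
half-open intervals [west, east) × [south, north). Capped subsamples and
MC seeds are derived from the run seed plus a checksum of the cell-set
content, so species with identical occupied cells get identical volumes.
Species with fewer than five distinct occupied cells are flagged and
assigned the minimum volume computed among unflagged species in the same
run (per replicate in capped mode).

Faith's PD uses the include-root convention: the PD of a single genus is
its root-to-tip path length. This keeps PD strictly positive and monotone
under set union, and matches the default of the standard implementations.

The nine-level dispersal score maps to three classes as 1–3 / 4–6 / 7–9;
the cut-points are uniform because no finer information is available, and
the mapping is isolated in one function should better cut-points emerge.

## The synthetic-data generator

The generator exists so that every downstream stage can be tested against
known truth. It emulates: a Yule tree conditioned on n tips (the final
n-lineage epoch is included, so the expected unit-rate root height is
Σ_{k=2..n} 1/k); latent predictors evolving under BM or OU along the tree,
exponentiated to positive right-skewed raw traits; an ordinal dispersal
class cut from a latent Brownian trait at the empirical quantiles of the
class marginals (269/89/11 over 369 species by default), preserving
phylogenetic signal in the ordinal trait; and log range size assembled as
intercept + β·x + ε with x the same transformed/standardized design the
pipeline reconstructs and ε multivariate normal with covariance
σ² exp(−α d). Range size is returned exponentiated so the pipeline's own
log transform is exercised.

Default coefficients are the standardized estimates of the butterfly
analysis (climate 1.56, diet 0.00, habitat 0.31, wingspan −0.06, ordinal
dispersal −0.07, intercept 14 ≈ log of a 10⁶ km² range). The residual
parameters are α = 10 and σ² = 2.0 on the unit-height tree: α = 10 sits in
the regime where the selection strength is statistically identifiable from
369 tips (at much larger α the OU correlation is effectively diagonal and
any estimator's relative error degrades), and σ² = 2.0 puts the total
predictive R² near 0.6, the order reported for real butterfly data. One
consequence is that the simulated BM-vs-OU likelihood-ratio statistic
(≈150) and the phylogeny partial R² (≈0.1–0.2) are closer to moderate
phylogenetic signal than the real data's more extreme values.

What the generator does **not** emulate: correlated predictors (traits are
independent given the shared tree), extinction (pure birth only),
measurement error in predictors, spatially structured occurrence sampling,
or the skewed cell-count distribution of real occurrence data. Passing
recovery tests therefore demonstrates the estimators are correct under the
assumed model, not that the model captures every feature of real
assemblages.

## Problem sizes

The test suite and the acceptance script run at the study scale of 369
species for single fits and parameter-recovery loops (200 replicates), a
100-tip tree for the 500-replicate likelihood-ratio calibration, and
80-tip trees for weighted-regression structure checks; hypervolume
validation uses 5000-point clouds. These sizes keep the full suite at a
few minutes on one CPU while leaving Monte-Carlo standard errors well
inside the asserted tolerances.

## Known limitations

- The OU structure is the plain exp(−α d) correlation also on
  non-ultrametric trees; no stationarity correction is applied there.
- The PWR bandwidth objective and effective-df CI convention are reasoned
  defaults; other choices (e.g. GCV bandwidths, sandwich SEs) are
  plausible and would change per-species classifications near the
  significance boundary.
- Hypervolume estimates assume the occupied niche region is compact;
  strongly multimodal clouds are bridged by the adaptive kernel at
  moderate n.
- `aggregate_grid` expects tabular regular grids (cell centres), not
  raster files; resolutions are degrees, weights cos(latitude).
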