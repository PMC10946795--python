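"""Decompose explained range-size variance across predictors.

Each predictor's partial predictive R^2 compares the full OU model with a
reduced model lacking that predictor (alpha held at the full-model
estimate); the phylogeny row compares the full phylogenetic model with a
non-phylogenetic OLS fit, and the full-model row with the intercept-only
null.
"""

from phylorange import SimulationConfig, simulate_range_dataset
from phylorange.gls import partial_r2_table

dataset = simulate_range_dataset(SimulationConfig(seed=7))
table = partial_r2_table(dataset.traits, dataset.tree)

print(table.round(3))
print()
print("Climate niche breadth carries the largest unique contribution, as")
print("planted in the generating coefficients; the near-zero rows match the")
print("predictors simulated with no effect on range size.")
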