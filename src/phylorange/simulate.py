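"""Synthetic data generation.

Everything the comparative pipeline consumes can be generated here with known
ground truth: Yule (pure-birth) phylogenies, continuous traits evolving under
Brownian motion or an Ornstein--Uhlenbeck process, full trait tables whose log
range size follows a linear model with phylogenetically correlated residuals,
occurrence point clouds with known 4-D volume, and host-plant genus trees with
per-species host assignments.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import phylo

__all__ = [
    "TraitModel",
    "SimulationConfig",
    "SyntheticDataset",
    "OccurrenceCloud",
    "simulate_yule_tree",
    "simulate_trait",
    "simulate_range_dataset",
    "simulate_occurrence_cloud",
    "simulate_host_data",
]

#: Continuous predictor columns of the trait table, in canonical order.
CONTINUOUS_PREDICTORS = ("climate_nb", "diet_nb", "habitat_nb", "wingspan_mm")
PREDICTORS = CONTINUOUS_PREDICTORS + ("dispersal_class",)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree conditioned on ``n_tips`` extant tips.

    The process starts at the root split with two lineages; while ``k``
    lineages are extant the next event time is exponential with rate
    ``k * birth_rate`` and a uniformly chosen lineage splits.  The final
    epoch (with ``n_tips`` lineages) is included before stopping, so the
    expected root height at unit birth rate is ``sum(1/k for k in 2..n)``.

    Tips are labelled ``t1..tn``.  Identical seeds give identical trees.
    """
    if n_tips < 3:
        raise ValueError(f"n_tips must be >= 3, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be positive, got {birth_rate}")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    active: list[dendropy.Node] = []
    start: dict[int, float] = {}
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        start[id(child)] = 0.0
        active.append(child)
    t = 0.0
    for k in range(2, n_tips + 1):
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_tips:
            break
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.edge.length = t - start.pop(id(node))
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            start[id(child)] = t
            active.append(child)
    for node in active:
        node.edge.length = t - start[id(node)]
    for i, node in enumerate(active):
        node.taxon = tns.new_taxon(f"t{i + 1}")
    return tree


def simulate_trait(
    tree: dendropy.Tree,
    model: str = "BM",
    sigma2: float = 1.0,
    alpha: float = 1.0,
    optimum: float = 0.0,
    root_state: Optional[float] = None,
    seed=0,
) -> pd.Series:
    """Simulate one continuous trait along the tree, one value per tip.

    ``model="BM"``: increments are Normal(0, sigma2 * branch_length).
    ``model="OU"``: the exact transition density is used on every branch --
    the mean decays towards ``optimum`` at rate ``alpha`` and the variance is
    ``sigma2/(2*alpha) * (1 - exp(-2*alpha*L))`` for a branch of length L.

    The root state defaults to ``optimum`` (the OU stationary mean).
    """
    if model not in ("BM", "OU"):
        raise ValueError(f"unknown trait model {model!r}; expected 'BM' or 'OU'")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if model == "OU" and alpha <= 0:
        raise ValueError("OU model requires alpha > 0")
    rng = _rng(seed)
    values: dict[int, float] = {
        id(tree.seed_node): optimum if root_state is None else root_state
    }
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        length = node.edge.length or 0.0
        if model == "BM":
            mean = parent
            var = sigma2 * length
        else:
            decay = np.exp(-alpha * length)
            mean = optimum + (parent - optimum) * decay
            var = sigma2 / (2.0 * alpha) * (1.0 - decay**2)
        values[id(node)] = mean + rng.normal() * np.sqrt(var)
    leaves = list(tree.leaf_node_iter())
    return pd.Series(
        [values[id(leaf)] for leaf in leaves],
        index=[leaf.taxon.label for leaf in leaves],
        name="trait",
    )


@dataclass(frozen=True)
class TraitModel:
    """Evolution model for one latent predictor: BM or OU along the tree."""

    model: str = "BM"
    sigma2: float = 1.0
    alpha: float = 1.0
    optimum: float = 0.0


def _default_trait_models() -> dict[str, TraitModel]:
    models = {name: TraitModel() for name in CONTINUOUS_PREDICTORS}
    # centre latent wingspan near ln(35) so raw values land on a mm scale
    models["wingspan_mm"] = TraitModel(optimum=3.55)
    return models


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth for a full synthetic comparative dataset.

    Defaults mirror the study conditions of the butterfly analysis: 369
    species; coefficients on the transformed/standardized predictor scale of
    (climate 1.56, diet 0.00, habitat 0.31, wingspan -0.06) plus an
    unstandardized ordinal dispersal coefficient of -0.07; dispersal-class
    marginals 269/89/11 over 369 species; and an OU residual with moderate
    phylogenetic signal on the unit-height tree.
    """

    n_tips: int = 369
    birth_rate: float = 1.0
    intercept: float = 14.0
    beta: Mapping[str, float] = field(
        default_factory=lambda: {
            "climate_nb": 1.56,
            "diet_nb": 0.00,
            "habitat_nb": 0.31,
            "dispersal_class": -0.07,
            "wingspan_mm": -0.06,
        }
    )
    resid_alpha: float = 10.0
    resid_sigma2: float = 2.0
    trait_models: Mapping[str, TraitModel] = field(default_factory=_default_trait_models)
    dispersal_probs: Sequence[float] = (269 / 369, 89 / 369, 11 / 369)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if self.resid_sigma2 <= 0:
            raise ValueError("resid_sigma2 must be positive")
        if self.resid_alpha < 0:
            raise ValueError("resid_alpha must be non-negative")
        probs = np.asarray(self.dispersal_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("dispersal_probs must be 3 non-negative values summing to 1")
        unknown = set(self.beta) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"beta names not among predictors: {sorted(unknown)}")
        for name, tm in self.trait_models.items():
            if name not in CONTINUOUS_PREDICTORS:
                raise ValueError(f"trait model for unknown predictor {name!r}")
            if tm.sigma2 <= 0:
                raise ValueError(f"trait model {name}: sigma2 must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta"] = dict(self.beta)
        d["trait_models"] = {k: dataclasses.asdict(v) for k, v in self.trait_models.items()}
        d["dispersal_probs"] = list(self.dispersal_probs)
        return d


@dataclass
class SyntheticDataset:
    """A simulated tree + trait table with the generating truth attached."""

    tree: dendropy.Tree
    traits: pd.DataFrame
    truth: SimulationConfig

    def write(self, tree_path, traits_path, truth_path=None) -> None:
        """Write the tree (Newick), trait table (TSV) and truth sidecar (JSON)."""
        phylo.write_newick(self.tree, tree_path)
        self.traits.to_csv(traits_path, sep="\t", index_label="species")
        if truth_path is not None:
            with open(truth_path, "w", encoding="utf-8") as fh:
                json.dump(self.truth.to_dict(), fh, indent=2, sort_keys=True)


def _ordinal_from_latent(latent: np.ndarray, probs: Sequence[float]) -> np.ndarray:
    """Threshold a latent trait at its empirical quantiles into classes 1..3.

    Using empirical quantiles keeps the class marginals at the requested
    proportions while the latent trait carries the phylogenetic signal.
    """
    cum = np.cumsum(probs)[:2]
    cuts = np.quantile(latent, cum)
    return 1 + np.searchsorted(cuts, latent, side="left").astype(int)


def simulate_range_dataset(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Simulate a complete comparative dataset from the generative model.

    Steps: a Yule tree rescaled to unit height; latent predictors evolved
    under the per-predictor BM/OU models and exponentiated to positive raw
    trait values; an ordinal dispersal class cut from a latent Brownian
    trait; and log range size built as ``intercept + beta . x + residual``
    where ``x`` are the square-root-transformed, standardized predictors
    (dispersal entering raw) and the residual is multivariate normal with
    covariance ``resid_sigma2 * exp(-resid_alpha * d_ij)``.  Range size is
    returned exponentiated (km^2) so the pipeline's own transform is
    exercised end to end.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, rng)
    phylo.scale_to_unit_height(tree)
    labels = phylo.tip_labels(tree)
    n = len(labels)

    traits = pd.DataFrame(index=pd.Index(labels, name="species"))
    design_cols = {}
    for name in CONTINUOUS_PREDICTORS:
        tm = config.trait_models.get(name, TraitModel())
        latent = simulate_trait(
            tree, tm.model, tm.sigma2, tm.alpha, tm.optimum, seed=rng
        ).to_numpy()
        raw = np.exp(latent)  # positive, right-skewed like real niche data
        traits[name] = raw
        col = np.sqrt(raw)
        design_cols[name] = (col - col.mean()) / col.std(ddof=1)

    disp_latent = simulate_trait(tree, "BM", 1.0, seed=rng).to_numpy()
    disp = _ordinal_from_latent(disp_latent, config.dispersal_probs)
    traits["dispersal_class"] = disp
    design_cols["dispersal_class"] = disp.astype(float)

    D = phylo.patristic_distances(tree).to_numpy()
    cov = config.resid_sigma2 * np.exp(-config.resid_alpha * D)
    resid = np.linalg.cholesky(cov + 1e-12 * np.eye(n)) @ rng.normal(size=n)

    log_range = config.intercept + resid
    for name, value in config.beta.items():
        log_range = log_range + value * design_cols[name]
    traits.insert(0, "range_size_km2", np.exp(log_range))
    traits = traits[
        ["range_size_km2", "climate_nb", "diet_nb", "habitat_nb", "dispersal_class", "wingspan_mm"]
    ]
    return SyntheticDataset(tree=tree, traits=traits, truth=config)


@dataclass(frozen=True)
class OccurrenceCloud:
    """A point cloud in 4-D niche space; ``true_volume`` is known for boxes."""

    points: np.ndarray
    true_volume: Optional[float]


def simulate_occurrence_cloud(
    n_points: int,
    sides: Optional[Sequence[float]] = None,
    gaussian_sd: Optional[Sequence[float]] = None,
    seed=0,
) -> OccurrenceCloud:
    """Draw ``n_points`` points in 4-D, uniform in a box or spherical Gaussian.

    Exactly one of ``sides`` (axis-aligned box side lengths; the true volume,
    their product, is recorded) or ``gaussian_sd`` (per-axis standard
    deviations; no finite support volume) must be given.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    if (sides is None) == (gaussian_sd is None):
        raise ValueError("specify exactly one of sides or gaussian_sd")
    rng = _rng(seed)
    if sides is not None:
        sides = np.asarray(sides, dtype=float)
        if sides.shape != (4,) or np.any(sides <= 0):
            raise ValueError("sides must be 4 positive lengths")
        pts = rng.uniform(0.0, 1.0, size=(n_points, 4)) * sides
        return OccurrenceCloud(points=pts, true_volume=float(np.prod(sides)))
    sd = np.asarray(gaussian_sd, dtype=float)
    if sd.shape != (4,) or np.any(sd <= 0):
        raise ValueError("gaussian_sd must be 4 positive values")
    return OccurrenceCloud(points=rng.normal(size=(n_points, 4)) * sd, true_volume=None)


def simulate_host_data(
    n_genera: int,
    n_species: int,
    mean_genera: float = 4.4,
    seed=0,
) -> tuple[dendropy.Tree, dict[str, set[str]]]:
    """Simulate a host-plant genus tree and per-species host-genus sets.

    The genus tree is Yule with tips ``g1..gN``.  Each species is assigned
    ``1 + Poisson(mean_genera - 1)`` genera (capped at ``n_genera``), drawn
    without replacement, so the mean host-genus count is ``mean_genera`` and
    every species has at least one host.
    """
    if n_genera < 3:
        raise ValueError("n_genera must be >= 3 (Yule tree needs >= 3 tips)")
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if mean_genera < 1:
        raise ValueError("mean_genera must be >= 1")
    rng = _rng(seed)
    host_tree = simulate_yule_tree(n_genera, 1.0, rng)
    for i, leaf in enumerate(host_tree.leaf_node_iter()):
        leaf.taxon.label = f"g{i + 1}"
    genera = np.array([leaf.taxon.label for leaf in host_tree.leaf_node_iter()])
    table: dict[str, set[str]] = {}
    for s in range(n_species):
        k = min(1 + int(rng.poisson(mean_genera - 1.0)), n_genera)
        table[f"s{s + 1}"] = set(rng.choice(genera, size=k, replace=False))
    return host_tree, table
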