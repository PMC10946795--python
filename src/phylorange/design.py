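"""Response/predictor transformations and the collinearity screen.

The regression relates log range size to three niche-breadth dimensions and
two dispersal indicators.  Continuous predictors (climate, diet and habitat
niche breadth, wingspan) are square-root transformed and standardized to zero
mean / unit SD; the ordinal dispersal class (1 = sedentary, 2 = moderately
mobile, 3 = dispersive) enters as an untransformed numeric column.  The
response is the natural logarithm of range size in km^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignMatrix", "prepare_design", "collinearity_screen"]

CONTINUOUS = ["climate_nb", "diet_nb", "habitat_nb", "wingspan_mm"]
ORDINAL = "dispersal_class"
RESPONSE = "range_size_km2"


@dataclass
class DesignMatrix:
    """Transformed response and predictors, with the constants to invert them."""

    y: pd.Series  # log range size
    X: pd.DataFrame  # intercept + transformed predictors, rows = species
    transform: dict = field(default_factory=dict)  # col -> (mean, sd) on sqrt scale

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.X.columns if c != "intercept"]

    def drop(self, column: str) -> "DesignMatrix":
        """The same design without one predictor column (for reduced models)."""
        if column not in self.predictors:
            raise KeyError(f"no predictor named {column!r}")
        return DesignMatrix(
            y=self.y, X=self.X.drop(columns=[column]), transform=dict(self.transform)
        )

    def invert(self) -> pd.DataFrame:
        """Reconstruct the raw trait table from the transformed design."""
        out = pd.DataFrame(index=self.X.index)
        out[RESPONSE] = np.exp(self.y)
        for col in CONTINUOUS:
            if col in self.X.columns:
                mean, sd = self.transform[col]
                out[col] = (self.X[col] * sd + mean) ** 2
        if ORDINAL in self.X.columns:
            out[ORDINAL] = self.X[ORDINAL].astype(int)
        return out


def prepare_design(traits: pd.DataFrame, climate_column: str = "climate_nb") -> DesignMatrix:
    """Build the regression design from a raw trait table.

    ``climate_column`` selects which climate-breadth column to use, so capped
    replicate columns (``climate_nb_rep1`` ...) can be swapped in for the
    constrained model fits; the design column is always named ``climate_nb``.
    """
    missing = [c for c in [RESPONSE, ORDINAL] + CONTINUOUS[1:] if c not in traits.columns]
    if climate_column not in traits.columns:
        missing.append(climate_column)
    if missing:
        raise KeyError(f"trait table is missing columns: {missing}")
    if traits.isna().any().any():
        bad = traits.columns[traits.isna().any()].tolist()
        raise ValueError(f"trait table has missing values in: {bad}")

    nonpos = traits.index[traits[RESPONSE] <= 0].tolist()
    if nonpos:
        raise ValueError(f"non-positive range size for species: {nonpos}")
    y = pd.Series(np.log(traits[RESPONSE].to_numpy(dtype=float)), index=traits.index, name="log_range_size")

    X = pd.DataFrame(index=traits.index)
    X["intercept"] = 1.0
    transform: dict[str, tuple[float, float]] = {}
    for col in CONTINUOUS:
        source = climate_column if col == "climate_nb" else col
        raw = traits[source].to_numpy(dtype=float)
        if np.any(raw < 0):
            raise ValueError(f"negative values in predictor {source!r}")
        root = np.sqrt(raw)
        mean, sd = root.mean(), root.std(ddof=1)
        if sd < 1e-12:
            raise ValueError(f"predictor {source!r} is constant; cannot standardize")
        X[col] = (root - mean) / sd
        transform[col] = (float(mean), float(sd))
    X[ORDINAL] = traits[ORDINAL].to_numpy(dtype=float)
    return DesignMatrix(y=y, X=X, transform=transform)


def collinearity_screen(design: DesignMatrix, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise predictor correlations with an inclusive flagging threshold.

    Pearson r between continuous pairs; Spearman rho for any pair involving
    the ordinal dispersal class.  Pairs with |coefficient| >= ``threshold``
    are flagged.
    """
    cols = design.predictors
    if len(cols) < 2:
        raise ValueError("need at least two predictor columns")
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            if ORDINAL in (a, b):
                coef = stats.spearmanr(design.X[a], design.X[b]).statistic
                kind = "spearman"
            else:
                coef = stats.pearsonr(design.X[a], design.X[b]).statistic
                kind = "pearson"
            rows.append(
                {
                    "var1": a,
                    "var2": b,
                    "method": kind,
                    "coefficient": float(coef),
                    "flagged": bool(abs(coef) >= threshold),
                }
            )
    return pd.DataFrame(rows)
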