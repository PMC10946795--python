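"""Phylogenetic generalized least squares and variance decomposition.

The inferential core: maximum-likelihood GLS under Brownian-motion or
Ornstein--Uhlenbeck residual structures, likelihood-ratio comparison of the
two, the predictive pseudo-R^2 of Ives (leave-one-out conditional
expectations under the fitted phylogenetic covariance), the drop-one partial
R^2 ladder with the OU alpha held at the full-model estimate, and
Burnham--Anderson averaging of coefficient estimates across the capped
climate-breadth replicate fits.

Estimation is ML (not REML) throughout so log-likelihoods of different
covariance structures are comparable in a likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from . import phylo
from .design import DesignMatrix, prepare_design

__all__ = [
    "GLSFit",
    "gls_fit",
    "fit_pgls_ml",
    "likelihood_ratio_test",
    "r2_pred",
    "partial_r2_table",
    "average_replicate_fits",
    "coefficient_table",
]

ALPHA_BRACKET = (1e-6, 50.0)  # in units of 1/root-height

#: Display names for the trait-table predictors in result tables.
PRETTY = {
    "climate_nb": "Climate niche breadth",
    "diet_nb": "Diet niche breadth",
    "habitat_nb": "Habitat niche breadth",
    "dispersal_class": "Dispersal tendency",
    "wingspan_mm": "Wingspan",
}


@dataclass
class GLSFit:
    """A fitted GLS model with everything needed for downstream comparisons."""

    beta: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    loglik: float
    sigma2: float
    model: str  # {"BM", "OU", "identity"}
    alpha: Optional[float]
    n: int
    p_dim: int
    n_params: int
    warning: Optional[str] = None
    # retained for R^2_pred and LRT consistency checks
    y_: np.ndarray = field(default=None, repr=False)
    X_: pd.DataFrame = field(default=None, repr=False)
    R_: np.ndarray = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "t": self.t, "p": self.p}
        )


def _gls_core(y: np.ndarray, X: np.ndarray, R: np.ndarray):
    """ML GLS given a fixed (up to scale) residual structure R.

    Returns (beta, cov_unit, sigma2_ml, loglik, resid).  ``cov_unit`` is
    (X' R^-1 X)^-1; the coefficient covariance is sigma2 * cov_unit.  The
    log-likelihood is invariant to the overall scaling of R because the ML
    sigma2 absorbs it.
    """
    n, p = X.shape
    try:
        c, low = linalg.cho_factor(R, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"residual structure not positive definite: {exc}")
    Ri_X = linalg.cho_solve((c, low), X, check_finite=False)
    Ri_y = linalg.cho_solve((c, low), y, check_finite=False)
    A = X.T @ Ri_X
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"design is rank deficient: X'R^-1X is singular (condition {cond:.2g})"
        )
    cov_unit = np.linalg.inv(A)
    beta = cov_unit @ (X.T @ Ri_y)
    resid = y - X @ beta
    q = float(resid @ (Ri_y - Ri_X @ beta))
    sigma2 = q / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    loglik = -0.5 * (n * (np.log(2.0 * np.pi) + np.log(sigma2) + 1.0) + logdet)
    return beta, cov_unit, sigma2, loglik, resid


def gls_fit(
    y,
    X: pd.DataFrame,
    R: np.ndarray,
    model: str = "custom",
    alpha: Optional[float] = None,
    n_extra_params: int = 0,
    warning: Optional[str] = None,
) -> GLSFit:
    """Fit GLS with a given residual correlation/covariance matrix ``R``.

    Coefficients are ``(X'R^-1X)^-1 X'R^-1 y``; the residual variance is the
    ML estimate ``e'R^-1e / n``; reported standard errors apply the
    ``n/(n-p)`` ML-to-unbiased adjustment, with t statistics on ``n - p``
    degrees of freedom.
    """
    names = list(X.columns)
    yv = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    Rv = np.asarray(R, dtype=float)
    n, p = Xv.shape
    if Rv.shape != (n, n):
        raise ValueError(f"R has shape {Rv.shape}, expected {(n, n)}")
    beta, cov_unit, sigma2, loglik, _ = _gls_core(yv, Xv, Rv)
    se = np.sqrt(np.diag(cov_unit) * sigma2 * n / (n - p))
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - p)
    idx = pd.Index(names)
    return GLSFit(
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        t=pd.Series(tval, index=idx),
        p=pd.Series(pval, index=idx),
        loglik=float(loglik),
        sigma2=float(sigma2),
        model=model,
        alpha=alpha,
        n=n,
        p_dim=p,
        n_params=p + 1 + n_extra_params,  # coefficients + sigma2 (+ alpha etc.)
        warning=warning,
        y_=yv,
        X_=X.copy(),
        R_=Rv,
    )


def fit_pgls_ml(
    y,
    X: pd.DataFrame,
    tree=None,
    model: str = "BM",
    alpha: Optional[float] = None,
    distances: Optional[np.ndarray] = None,
) -> GLSFit:
    """ML phylogenetic GLS under a BM or OU residual structure.

    BM uses the shared-path covariance of the tree directly.  OU profiles
    the log-likelihood over the selection strength alpha with a bounded
    scalar search on ``[1e-6/H, 50/H]`` (H = root height) unless ``alpha``
    is supplied, in which case the structure is fixed at that value (used by
    the drop-one ladder, which holds alpha at the full-model estimate).

    ``distances`` may carry a precomputed patristic-distance matrix aligned
    with the rows of ``X`` to avoid recomputation in replicate loops.
    """
    if model not in ("BM", "OU"):
        raise ValueError(f"unknown evolution model {model!r}")
    if model == "BM":
        V = phylo.bm_covariance(tree)
        _check_alignment(X, V.index)
        return gls_fit(y, X, V.to_numpy(), model="BM")

    if distances is None:
        Dm = phylo.patristic_distances(tree)
        _check_alignment(X, Dm.index)
        D = Dm.to_numpy()
        H = float(np.max(phylo.bm_covariance(tree).to_numpy().diagonal()))
    else:
        D = np.asarray(distances, dtype=float)
        H = float(D.max() / 2.0)
    yv = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)

    if alpha is not None:
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        return gls_fit(
            y, X, np.exp(-alpha * D), model="OU", alpha=alpha, n_extra_params=1
        )

    lo, hi = ALPHA_BRACKET[0] / H, ALPHA_BRACKET[1] / H

    def neg_profile(a: float) -> float:
        return -_gls_core(yv, Xv, np.exp(-a * D))[3]

    res = optimize.minimize_scalar(
        neg_profile, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8 * hi}
    )
    a_hat = float(res.x)
    warning = None
    tol = 1e-6 * hi
    if a_hat - lo < tol or hi - a_hat < tol:
        warning = f"alpha estimate {a_hat:.3g} at search boundary [{lo:.3g}, {hi:.3g}]"
    return gls_fit(
        y, X, np.exp(-a_hat * D), model="OU", alpha=a_hat, n_extra_params=1,
        warning=warning,
    )


def _check_alignment(X: pd.DataFrame, labels) -> None:
    if list(X.index) != list(labels):
        raise ValueError("rows of the design are not aligned with the tree tips")


def likelihood_ratio_test(fit_null: GLSFit, fit_alt: GLSFit) -> dict:
    """Likelihood-ratio test of nested residual structures on the same data."""
    if fit_null.n != fit_alt.n or not np.allclose(fit_null.y_, fit_alt.y_):
        raise ValueError("fits are not on the same response; cannot compare")
    if list(fit_null.X_.columns) != list(fit_alt.X_.columns):
        raise ValueError("fits have different design matrices; cannot compare")
    df = fit_alt.n_params - fit_null.n_params
    if df <= 0:
        raise ValueError("alternative model must have more parameters than the null")
    chi2 = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    return {"chi2": chi2, "df": df, "p": float(stats.chi2.sf(chi2, df))}


def _loo_residuals(fit: GLSFit) -> np.ndarray:
    """Observed minus leave-one-out conditional expectation, per species.

    With Sigma = sigma2 * R and e the GLS residual, the conditional
    prediction for species i given all others is
    ``x_i beta + Sigma_{i,-i} Sigma_{-i,-i}^{-1} e_{-i}``; the resulting
    residual equals ``(R^-1 e)_i / (R^-1)_{ii}`` (sigma2 cancels).  For an
    identity structure this is the ordinary residual.
    """
    e = fit.y_ - fit.X_.to_numpy(dtype=float) @ fit.beta.to_numpy()
    Ri = np.linalg.inv(fit.R_)
    return (Ri @ e) / np.diag(Ri)


def r2_pred(fit_full: GLSFit, fit_reduced: Optional[GLSFit] = None) -> float:
    """Predictive pseudo-R^2: 1 - Var(y - yhat_full) / Var(y - yhat_reduced).

    Predictions are leave-one-out conditional expectations under each fit's
    phylogenetic covariance.  ``fit_reduced=None`` compares against the OLS
    intercept-only null, whose prediction is the sample mean.  The raw value
    is returned un-floored (it can be slightly negative for a full model no
    better than the reduced one).
    """
    r_full = _loo_residuals(fit_full)
    if fit_reduced is None:
        r_red = fit_full.y_ - fit_full.y_.mean()
    else:
        if fit_full.n != fit_reduced.n or not np.allclose(fit_full.y_, fit_reduced.y_):
            raise ValueError("fits are not on the same response")
        r_red = _loo_residuals(fit_reduced)
    denom = float(np.var(r_red))
    if denom <= 0:
        raise ZeroDivisionError("reduced-model residual variance is zero; R^2 undefined")
    return 1.0 - float(np.var(r_full)) / denom


def _fit_ladder(design: DesignMatrix, tree, distances: np.ndarray) -> dict:
    """Full OU fit plus drop-one reduced fits at the full model's alpha."""
    full = fit_pgls_ml(design.y, design.X, tree, model="OU", distances=distances)
    out = {"full": full, "partials": {}, "alpha": full.alpha}
    for col in design.predictors:
        reduced = fit_pgls_ml(
            design.y, design.drop(col).X, tree, model="OU",
            alpha=full.alpha, distances=distances,
        )
        out["partials"][col] = r2_pred(full, reduced)
    identity = np.eye(full.n)
    ols_full = gls_fit(design.y, design.X, identity, model="identity")
    out["phylogeny"] = r2_pred(full, ols_full)
    out["total"] = r2_pred(full)
    return out


def partial_r2_table(
    traits: pd.DataFrame,
    tree,
    cap_mode: str = "unconstrained",
    replicate_columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Variance decomposition of the full model (written as ``table1.tsv``).

    ``unconstrained`` uses the ``climate_nb`` column; ``constrained``
    repeats the whole ladder once per capped climate-breadth replicate
    column (``climate_nb_rep*`` by default), each replicate re-estimating
    its own full-model alpha, and reports mean (min-max) across replicates.
    Reported values are floored at zero; a ``raw`` column keeps the
    unfloored numbers in unconstrained mode.
    """
    D = phylo.patristic_distances(tree)
    rows = ["Full model"] + [PRETTY[c] for c in
                             ["climate_nb", "diet_nb", "habitat_nb", "dispersal_class", "wingspan_mm"]] + ["Phylogeny"]

    def ladder_values(climate_column: str) -> dict[str, float]:
        traits_aligned = traits.loc[list(D.index)]
        design = prepare_design(traits_aligned, climate_column=climate_column)
        lad = _fit_ladder(design, tree, D.to_numpy())
        vals = {"Full model": lad["total"], "Phylogeny": lad["phylogeny"]}
        for col, r2 in lad["partials"].items():
            vals[PRETTY[col]] = r2
        return vals

    if cap_mode == "unconstrained":
        vals = ladder_values("climate_nb")
        raw = pd.Series({r: vals[r] for r in rows})
        return pd.DataFrame({"r2": raw.clip(lower=0.0), "raw": raw})
    if cap_mode != "constrained":
        raise ValueError(f"unknown cap_mode {cap_mode!r}")

    if replicate_columns is None:
        replicate_columns = sorted(
            (c for c in traits.columns if c.startswith("climate_nb_rep")),
            key=lambda c: int(c.rsplit("rep", 1)[1]),
        )
    if not replicate_columns:
        raise ValueError("constrained mode needs climate_nb_rep* columns in the trait table")
    reps = pd.DataFrame([ladder_values(c) for c in replicate_columns])
    reps = reps[rows].clip(lower=0.0)
    return pd.DataFrame(
        {"mean": reps.mean(), "min": reps.min(), "max": reps.max()}
    ).loc[rows]


def average_replicate_fits(fits: Sequence[GLSFit]) -> pd.DataFrame:
    """Average coefficients over replicate fits with model-averaged SEs.

    Estimates are means across fits; the standard error of each coefficient
    is ``(1/m) * sum_i sqrt(se_i^2 + (est_i - mean)^2)`` (equal-weight
    unconditional SE), and p-values come from t statistics on the averaged
    estimate and SE with ``n - p`` degrees of freedom.
    """
    if not fits:
        raise ValueError("no fits to average")
    names = list(fits[0].beta.index)
    for f in fits[1:]:
        if list(f.beta.index) != names:
            raise ValueError("fits have mismatched coefficient sets")
    est = np.array([f.beta.to_numpy() for f in fits])
    se = np.array([f.se.to_numpy() for f in fits])
    mean = est.mean(axis=0)
    avg_se = np.mean(np.sqrt(se**2 + (est - mean) ** 2), axis=0)
    tval = mean / avg_se
    df = fits[0].n - fits[0].p_dim
    pval = 2.0 * stats.t.sf(np.abs(tval), df=df)
    return pd.DataFrame(
        {"estimate": mean, "se": avg_se, "t": tval, "p": pval}, index=pd.Index(names)
    )


def coefficient_table(fit: GLSFit) -> pd.DataFrame:
    """Coefficient summary with display names (written as ``table2.tsv``)."""
    out = fit.summary()
    out.index = [PRETTY.get(name, name) for name in out.index]
    return out
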