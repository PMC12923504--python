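"""Empirical input surfaces from the field tables.

The sampling design is nested (replicates within subsites within transects
within sites), so responses are modelled with a linear mixed model carrying
a random intercept per site: biomass against elevation (optionally plus
porewater salinity), and inorganic TSS against northing. Candidate
fixed-effect sets are compared by AIC computed from *maximum-likelihood*
fits — REML likelihoods are not comparable across different fixed effects —
and the winning fit is projected onto the grid at the population level
(random intercept zero), truncated at physical zero.

Fitting is delegated to :class:`statsmodels` ``MixedLM``; this module owns
the degenerate noise-free path, the AIC bookkeeping, and the projection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .grid import Grid

#: Variance floor used only to keep the log-likelihood finite when the
#: response is an exact linear function of the covariates.
_SIGMA2_FLOOR = 1e-12


@dataclass(frozen=True)
class LMMFit:
    """A fitted random-intercept linear mixed model."""

    response: str
    fixed_effects: tuple[str, ...]        # covariate names, intercept excluded
    coefficients: dict[str, float]        # includes "intercept"
    standard_errors: dict[str, float]
    group: str
    group_variance: float
    residual_variance: float
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool = True
    degenerate: bool = False              # exact-fit (zero variance) path

    @property
    def k_fixed(self) -> int:
        return len(self.fixed_effects) + 1  # + intercept

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {k: getattr(self, k) for k in (
            "response", "coefficients", "standard_errors", "group",
            "group_variance", "residual_variance", "loglik", "aic",
            "n_obs", "n_groups", "converged", "degenerate")}
        payload["fixed_effects"] = list(self.fixed_effects)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _design(table: pd.DataFrame, response: str,
            fixed: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    y = table[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(table))]
                        + [table[c].to_numpy(dtype=float) for c in fixed])
    return y, X


def fit_lmm(table: pd.DataFrame, response: str,
            fixed_covariates: "list[str] | tuple[str, ...]",
            group: str = "site") -> LMMFit:
    """Fit ``response ~ fixed_covariates`` with a random intercept per group.

    Maximum-likelihood estimation (``reml=False``); AIC is computed as
    ``-2 loglik + 2 k`` with ``k`` counting the fixed effects (intercept
    included) plus the two variance components. Deterministic given the
    table, and invariant to row order.

    Raises
    ------
    ValueError
        For fewer than two groups (the random intercept is unidentifiable),
        constant covariates, or a singular fixed-effects design.
    """
    fixed = tuple(fixed_covariates)
    for col in (response, group, *fixed):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    # Canonical row order (stable sort by group) so estimates do not depend
    # on how the table happens to be sorted.
    table = table.sort_values(group, kind="stable")
    groups = table[group].to_numpy()
    n_groups = len(pd.unique(groups))
    if n_groups < 2:
        raise ValueError("need >= 2 groups: random intercept unidentifiable")
    y, X = _design(table, response, fixed)
    for name, col in zip(fixed, X[:, 1:].T):
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effects design")
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few observations for the requested model")

    # Exact-fit pre-check: with zero site and residual noise the ML problem
    # is degenerate (likelihood unbounded), so solve by least squares and
    # report zero variances with a floored likelihood.
    beta, ssr_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(ssr_arr[0]) if ssr_arr.size else float(
        ((y - X @ beta) ** 2).sum())
    scale = float(np.var(y)) if np.var(y) > 0 else 1.0
    n = len(y)
    if ssr / (n * scale) < 1e-14:
        sigma2 = _SIGMA2_FLOOR
        llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + ssr / (n * sigma2))
        k = len(fixed) + 1 + 2
        coef = {"intercept": float(beta[0])}
        coef.update({nm: float(b) for nm, b in zip(fixed, beta[1:])})
        ses = {nm: 0.0 for nm in coef}
        return LMMFit(response, fixed, coef, ses, group, 0.0, 0.0,
                      float(llf), float(-2.0 * llf + 2.0 * k), n, n_groups,
                      converged=True, degenerate=True)

    # Reporting follows the field convention: REML estimates and standard
    # errors (less biased variance components with few groups), with the
    # log-likelihood and AIC taken from an ML refit so AIC stays comparable
    # across fixed-effect sets.
    reml_fit = _robust_mixedlm(y, X, groups, reml=True)
    ml_fit = _robust_mixedlm(y, X, groups, reml=False)
    params = np.asarray(reml_fit.fe_params, dtype=float)
    bse = np.asarray(reml_fit.bse_fe, dtype=float)
    coef = {"intercept": float(params[0])}
    coef.update({nm: float(b) for nm, b in zip(fixed, params[1:])})
    ses = {"intercept": float(bse[0])}
    ses.update({nm: float(s) for nm, s in zip(fixed, bse[1:])})
    llf = float(ml_fit.llf)
    k = len(fixed) + 1 + 2
    return LMMFit(
        response, fixed, coef, ses, group,
        group_variance=float(np.asarray(reml_fit.cov_re)[0, 0]),
        residual_variance=float(reml_fit.scale),
        loglik=llf, aic=float(-2.0 * llf + 2.0 * k),
        n_obs=n, n_groups=n_groups,
        converged=bool(reml_fit.converged and ml_fit.converged),
    )


def _robust_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray,
                    reml: bool):
    """Fit MixedLM, guarding against degenerate optimizer terminations.

    The default optimizer occasionally stops on a boundary with an infinite
    likelihood and garbage coefficients; validate the result and fall back
    through alternative optimizers, keeping the best finite-likelihood fit.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (None, "powell", "bfgs"):
            model = MixedLM(y, X, groups=groups)
            try:
                cand = model.fit(reml=reml) if method is None \
                    else model.fit(reml=reml, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            llf = float(cand.llf)
            bse = np.asarray(cand.bse_fe, dtype=float)
            if np.isfinite(llf) and np.isfinite(bse).all():
                if best is None or llf > float(best.llf) + 1e-10:
                    best = cand
            if best is not None and method == "powell" and best.converged:
                break  # default + powell agree on a finite optimum
    if best is None:
        raise ValueError("mixed-model fit failed on every optimizer")
    return best


def select_by_aic(fits: "list[LMMFit]") -> LMMFit:
    """Return the fit with the lowest AIC; ties go to fewer fixed effects."""
    if not fits:
        raise ValueError("no candidate fits")
    responses = {f.response for f in fits}
    n_obs = {f.n_obs for f in fits}
    if len(responses) > 1 or len(n_obs) > 1:
        raise ValueError("candidates must share response and data")
    return min(fits, key=lambda f: (f.aic, f.k_fixed))


#: How fitted covariate names map onto per-cell values.
_GRID_COVARIATES = ("elevation", "elevation_m", "northing", "easting")


def predict_surface(fit: LMMFit, dem: Grid) -> Grid:
    """Project a fit onto the grid as a population-level surface.

    Covariates named ``elevation``/``elevation_m`` read the DEM values;
    ``northing``/``easting`` read cell-center coordinates from the grid
    geometry. The random intercept is set to zero (grid cells are
    unobserved sites), predictions are truncated at zero, and NODATA cells
    propagate.
    """
    meta = dem.meta
    elev = np.asarray(dem.data, dtype=float)
    easting, northing = meta.cell_centers()
    values = {"elevation": elev, "elevation_m": elev,
              "northing": northing, "easting": easting}
    pred = np.full(meta.shape, fit.coefficients["intercept"], dtype=float)
    for name in fit.fixed_effects:
        if name not in values:
            raise KeyError(
                f"covariate {name!r} is not computable from grid metadata "
                f"(available: {sorted(set(_GRID_COVARIATES))})")
        pred = pred + fit.coefficients[name] * values[name]
    pred = np.maximum(pred, 0.0)
    invalid = ~dem.valid_mask
    pred[invalid] = meta.nodata
    return Grid(pred, meta)
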