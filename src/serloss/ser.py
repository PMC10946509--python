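"""Species–energy model: stratified wilderness sampling and quasi-Poisson fit.

Calibration draws a stratified sample of wilderness cells (a fixed quota
per realm, reduced to a third of the available cells in wilderness-poor
realms to temper spatial autocorrelation, with the global NPP_pot extremes
force-included to avoid extrapolation) and regresses potential richness on
NPP_pot plus realm and mainland–island intercepts with a log-link Poisson
GLM. Overdispersion is absorbed quasi-likelihood style: the Pearson
dispersion scales the standard errors, leaving point estimates untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, FitError, PipelineError, SingularDesignError
from .wilderness import WildernessMask
from .world import World

__all__ = ["SampleSpec", "FittedSER", "stratified_sample", "build_design",
           "fit_quasipoisson", "fit_ser", "adjusted_r2", "partial_r2"]

TermGroup = Literal["npp", "realm", "island"]


@dataclass(frozen=True)
class SampleSpec:
    """Stratified-sampling protocol for the calibration sample."""

    n_per_realm: int = 500
    small_realm_fraction: float = 1.0 / 3.0
    force_extremes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_realm < 1:
            raise ConfigError("n_per_realm must be >= 1")
        if not (0.0 < self.small_realm_fraction <= 1.0):
            raise ConfigError("small_realm_fraction must lie in (0, 1]")


@dataclass
class FittedSER:
    """Quasi-Poisson species–energy fit with dispersion and fit summaries."""

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    dispersion_phi: float
    deviance_null: float
    deviance_resid: float
    df_null: int
    df_resid: int
    adjusted_r2: float
    partial_r2: dict[str, float]
    sample: list[tuple[int, int]]
    realm_levels: tuple[int, ...]
    reference_realm: int
    # retained for refits (partial R2) and projection
    response: np.ndarray = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)

    @property
    def beta_npp(self) -> float:
        return self.coefficients["npp"]

    @property
    def se_npp(self) -> float:
        return self.standard_errors["npp"]

    def linear_predictor(self, realm: np.ndarray, island: np.ndarray,
                         npp: np.ndarray,
                         beta_npp_override: float | None = None) -> np.ndarray:
        """Evaluate the fitted log-scale predictor on grids.

        Cells whose realm was not in the fitted levels evaluate to NaN.
        """
        beta_npp = self.beta_npp if beta_npp_override is None else beta_npp_override
        eta = np.full(realm.shape, np.nan)
        for r in self.realm_levels:
            sel = realm == r
            off = 0.0 if r == self.reference_realm else self.coefficients[f"realm_{r}"]
            eta[sel] = self.coefficients["intercept"] + off
        eta = eta + self.coefficients["island"] * island.astype(float) + beta_npp * npp
        return eta


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_sample(mask: WildernessMask, realm: np.ndarray, npp_pot: np.ndarray,
                      spec: SampleSpec,
                      kept_realms: tuple[int, ...] | None = None) -> list[tuple[int, int]]:
    """Draw the stratified calibration sample of wilderness cells.

    Per kept realm: ``n_per_realm`` cells where the realm has at least that
    many wilderness cells, otherwise round(small_realm_fraction × count)
    (at least 1), without replacement. With ``force_extremes`` the
    wilderness cells holding the global minimum and maximum NPP_pot are
    swapped in for random picks of their realms, leaving quotas intact.
    """
    spec.validate()
    wild = mask.wilderness
    if kept_realms is None:
        kept_realms = tuple(int(r) for r in np.unique(realm[realm > 0])
                            if (wild & (realm == r)).any())
    rng = np.random.default_rng(spec.seed)
    ncols = realm.shape[1]
    chosen: list[int] = []
    realm_slots: dict[int, tuple[int, int]] = {}
    for r in sorted(kept_realms):
        flat = np.flatnonzero((wild & (realm == r)).ravel())
        w_r = len(flat)
        if w_r == 0:
            raise PipelineError(
                f"realm {r} has no wilderness cells; it should have been excluded upstream")
        quota = spec.n_per_realm if w_r >= spec.n_per_realm \
            else max(1, _round_half_up(spec.small_realm_fraction * w_r))
        picks = rng.choice(flat, size=quota, replace=False)
        realm_slots[r] = (len(chosen), len(chosen) + quota)
        chosen.extend(int(p) for p in picks)

    if spec.force_extremes:
        wflat = np.flatnonzero(wild.ravel() & np.isin(realm.ravel(), kept_realms))
        vals = npp_pot.ravel()[wflat]
        extremes = [int(wflat[vals.argmin()]), int(wflat[vals.argmax()])]
        for ext in extremes:
            if ext in chosen:
                continue
            r = int(realm.ravel()[ext])
            lo, hi = realm_slots[r]
            replaceable = [i for i in range(lo, hi) if chosen[i] not in extremes]
            chosen[int(rng.choice(replaceable))] = ext
    return [divmod(c, ncols) for c in chosen]


def build_design(cells: list[tuple[int, int]], world: World,
                 sr_pot_wilderness: np.ndarray,
                 kept_realms: tuple[int, ...] | None = None
                 ) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Assemble response and design matrix for the SER regression.

    Treatment coding: one shared intercept (reference = first kept realm,
    mainland), one contrast per further realm, a binary island effect and a
    single shared NPP_pot slope.
    """
    rr = np.array([c[0] for c in cells])
    cc = np.array([c[1] for c in cells])
    y = sr_pot_wilderness[rr, cc]
    if np.isnan(y).any():
        raise ConfigError("sampled cells must have defined wilderness SR_pot")
    y = y.astype(np.int64)
    realms_here = np.unique(world.realm[rr, cc])
    if kept_realms is None:
        levels = tuple(int(r) for r in realms_here)
    else:
        levels = tuple(sorted(kept_realms))
        missing = set(levels) - set(int(r) for r in realms_here)
        if missing:
            import warnings
            warnings.warn(f"realm level(s) {sorted(missing)} kept for projection but "
                          "absent from the sample: projections there extrapolate")
            levels = tuple(int(r) for r in realms_here)
    reference = levels[0]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cells))}
    rvals = world.realm[rr, cc]
    for r in levels[1:]:
        cols[f"realm_{r}"] = (rvals == r).astype(float)
    cols["island"] = world.island[rr, cc].astype(float)
    cols["npp"] = world.npp_pot[rr, cc]
    X = pd.DataFrame(cols)
    meta = {"realm_levels": levels, "reference_realm": reference,
            "cells": [(int(a), int(b)) for a, b in zip(rr, cc)]}
    return y, X, meta


def fit_quasipoisson(response: np.ndarray, design: pd.DataFrame,
                     meta: dict | None = None,
                     compute_partial: bool = True) -> FittedSER:
    """Fit the log-link quasi-Poisson GLM.

    Point estimates are plain Poisson maximum likelihood (IRLS, relative
    deviance tolerance 1e-8, at most 100 iterations); the Pearson dispersion
    φ = χ²/(n−p) rescales standard errors by √φ.
    """
    y = np.asarray(response)
    if np.any(y < 0):
        raise ConfigError("response must be non-negative counts")
    X = design
    n, p = X.shape
    if n <= p:
        raise FitError(f"need n > p to fit; got n={n}, p={p}")
    if np.linalg.matrix_rank(X.to_numpy()) < p:
        raise SingularDesignError(f"design matrix is rank deficient (p={p})")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(maxiter=100, tol=1e-8, tol_criterion="deviance")
    except TypeError:  # older statsmodels without tol_criterion
        res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise FitError(f"IRLS did not converge in 100 iterations "
                       f"(deviance trace tail: {res.fit_history['deviance'][-3:]})")
    phi = float(res.pearson_chi2 / res.df_resid)
    coefs = dict(zip(X.columns, (float(v) for v in res.params)))
    base_se = np.sqrt(np.diag(res.cov_params()))
    ses = dict(zip(X.columns, (float(s * np.sqrt(phi)) for s in base_se)))
    tvals = {k: (coefs[k] / ses[k] if ses[k] > 0 else np.nan) for k in coefs}
    meta = meta or {}
    fit = FittedSER(
        coefficients=coefs, standard_errors=ses, t_values=tvals, dispersion_phi=phi,
        deviance_null=float(res.null_deviance), deviance_resid=float(res.deviance),
        df_null=n - 1, df_resid=int(res.df_resid), adjusted_r2=np.nan, partial_r2={},
        sample=meta.get("cells", []),
        realm_levels=tuple(meta.get("realm_levels", ())),
        reference_realm=meta.get("reference_realm", 0),
        response=y, design=X)
    fit.adjusted_r2 = adjusted_r2(fit)
    if compute_partial:
        fit.partial_r2 = {g: partial_r2(fit, g) for g in ("npp", "realm", "island")
                          if _group_columns(X, g)}
    return fit


def _group_columns(X: pd.DataFrame, group: TermGroup) -> list[str]:
    if group == "npp":
        return [c for c in X.columns if c == "npp"]
    if group == "island":
        return [c for c in X.columns if c == "island"]
    if group == "realm":
        return [c for c in X.columns if c.startswith("realm_")]
    raise ConfigError(f"unknown term group {group!r}")


def adjusted_r2(fit: FittedSER) -> float:
    """Deviance-based adjusted R²: 1 − (D_res/df_res)/(D_null/df_null)."""
    if fit.df_resid <= 0:
        raise FitError("adjusted R2 undefined with zero residual degrees of freedom")
    if fit.deviance_null == 0:
        return 0.0
    return 1.0 - (fit.deviance_resid / fit.df_resid) / (fit.deviance_null / fit.df_null)


def partial_r2(fit: FittedSER, term_group: TermGroup) -> float:
    """Deviance uniquely explained by a term group.

    (D_reduced − D_full) / D_reduced, with the reduced model refitted on
    the identical sample without the group's columns.
    """
    drop = _group_columns(fit.design, term_group)
    if not drop:
        raise ConfigError(f"term group {term_group!r} not present in the design")
    X_red = fit.design.drop(columns=drop)
    res = sm.GLM(fit.response, X_red, family=sm.families.Poisson()).fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise FitError(f"reduced model (without {term_group}) did not converge")
    d_red = float(res.deviance)
    if d_red == 0:
        return 0.0
    return (d_red - fit.deviance_resid) / d_red


def fit_ser(world: World, sr_pot_wilderness: np.ndarray, mask: WildernessMask,
            spec: SampleSpec, kept_realms: tuple[int, ...] | None = None) -> FittedSER:
    """Convenience wrapper: sample, build the design, and fit."""
    cells = stratified_sample(mask, world.realm, world.npp_pot, spec, kept_realms)
    y, X, meta = build_design(cells, world, sr_pot_wilderness, kept_realms)
    return fit_quasipoisson(y, X, meta)
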