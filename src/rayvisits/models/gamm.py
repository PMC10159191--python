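"""Gamma GAMM for visit duration.

Penalized-spline additive model on statsmodels' GLMGam machinery: cyclic
cubic splines for decimal hour (0 == 24), B-splines for the remaining
continuous covariates, parametric tide-state and general-location terms,
and a ridge-penalized per-animal intercept playing the role of a random
effect (the classic smooth-term representation of a random intercept).
The Gamma family is fit with the inverse link first; if that fails to
produce a valid fit the model is refit with a log link and flagged.

Smoothing weights are chosen by generalized cross-validation via
coordinate descent on a log-spaced grid.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import GLMGam
from statsmodels.gam.smooth_basis import (
    GenericSmoothers,
    UnivariateBSplines,
    UnivariateCubicCyclicSplines,
    UnivariateGamSmoother,
)

DEFAULT_SMOOTHS = (
    "decimal_hour",
    "moon_fraction",
    "water_temp_c",
    "salinity",
    "do_mg_l",
)
DEFAULT_PARAMETRIC = ("tide_state", "general_location")
CYCLIC_TERMS = {"decimal_hour"}


class RandomInterceptSmoother(UnivariateGamSmoother):
    """Group dummies with an identity penalty: a random intercept as a smooth.

    Penalizing the one-hot group basis by its squared norm is exactly the
    ridge shrinkage a Gaussian random intercept induces; the smoothing
    weight maps to the variance ratio (scale / sigma_u^2).
    """

    def __init__(self, codes, n_levels: int, variable_name: str = "group"):
        self.n_levels = int(n_levels)
        super().__init__(
            np.asarray(codes, dtype=float), constraints=None, variable_name=variable_name
        )

    def _smooth_basis_for_single_variable(self):
        basis = np.zeros((self.nobs, self.n_levels))
        basis[np.arange(self.nobs), self.x.astype(int)] = 1.0
        zeros = np.zeros_like(basis)
        return basis, zeros, zeros, np.eye(self.n_levels)

    def transform(self, x_new):
        x_new = np.asarray(x_new, dtype=float)
        out = np.zeros((len(x_new), self.n_levels))
        out[np.arange(len(x_new)), x_new.astype(int)] = 1.0
        return out


@dataclasses.dataclass
class GammResult:
    """Summary of a fitted visit-duration GAMM."""

    results: object  # GLMGamResults
    smooth_terms: list[str]
    parametric_terms: list[str]
    term_edf: pd.Series
    term_pvalues: pd.Series
    parametric_table: pd.DataFrame
    link: str
    link_fallback: bool
    alpha: dict[str, float]
    loglike: float
    edf_total: float
    n_obs: int
    group_term: str = "transmitter_id"

    @property
    def aicc(self) -> float:
        return aicc(self.loglike, self.edf_total + 1.0, self.n_obs)

    def partial_effect(self, term: str, grid: np.ndarray) -> np.ndarray:
        """Centered smooth-term contribution on the link scale over a grid."""
        i = self.smooth_terms.index(term)
        model = self.results.model
        smoother = model.smoother.smoothers[i]
        mask = model.smoother.mask[i]
        idx = model.k_exog_linear + np.nonzero(mask)[0]
        basis = smoother.transform(np.asarray(grid, dtype=float))
        vals = basis @ self.results.params[idx]
        return vals - vals.mean()


def aicc(llf: float, k: float, n: int) -> float:
    """Small-sample corrected AIC; +inf when the correction denominator dies."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def _build_smoothers(
    data: pd.DataFrame,
    smooth_terms: Sequence[str],
    group: str | None,
    df: int,
) -> tuple[GenericSmoothers, list[str], pd.Index | None]:
    parts = []
    xcols = []
    names = []
    for term in smooth_terms:
        x = data[term].to_numpy(dtype=float)
        if term in CYCLIC_TERMS:
            parts.append(UnivariateCubicCyclicSplines(x, df=df, variable_name=term))
        else:
            parts.append(
                UnivariateBSplines(x, df=df, degree=3, variable_name=term)
            )
        xcols.append(x)
        names.append(term)
    group_levels = None
    if group is not None:
        codes, group_levels = pd.factorize(data[group])
        parts.append(
            RandomInterceptSmoother(codes, len(group_levels), variable_name=group)
        )
        xcols.append(codes.astype(float))
        names.append(group)
    sm_obj = GenericSmoothers(np.column_stack(xcols), parts)
    return sm_obj, names, group_levels


def _design_parametric(
    data: pd.DataFrame, parametric_terms: Sequence[str]
) -> pd.DataFrame:
    exog = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    for term in parametric_terms:
        vals = data[term].astype(str)
        for lv in sorted(vals.unique())[1:]:
            exog[f"{term}[{lv}]"] = (vals == lv).astype(float)
    return exog


def _fit_once(endog, exog, smoother, alpha_vec, link):
    links = {"inverse": sm.families.links.InversePower(), "log": sm.families.links.Log()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        family = sm.families.Gamma(link=links[link])
        model = GLMGam(
            endog, exog=exog.to_numpy(), smoother=smoother, alpha=alpha_vec, family=family
        )
        model.exog_names[: exog.shape[1]] = list(exog.columns)
        res = model.fit(method="pirls", maxiter=200)
    mu = res.fittedvalues
    if not (np.all(np.isfinite(res.params)) and np.all(mu > 0) and np.isfinite(res.scale)):
        raise ValueError("invalid fit")
    # per-column effective df of a well-conditioned penalized fit lies in
    # [0, 1]; small excursions are round-off, but values far outside flag a
    # numerically singular system whose AICc would be meaningless
    edf = np.asarray(res.edf, dtype=float)
    if not (
        np.all(np.isfinite(edf))
        and np.all(edf > -0.5)
        and np.all(edf < 1.6)
        and 0 < edf.sum() < 0.9 * len(endog)
    ):
        raise ValueError("invalid fit: degenerate effective degrees of freedom")
    return model, res


def _gcv(res, n: int) -> float:
    edf = float(res.edf.sum())
    if n - edf <= 0:
        return np.inf
    return n * float(res.deviance) / (n - edf) ** 2


def fit_visit_gamm(
    visits: pd.DataFrame,
    response: str = "duration_min",
    smooth_terms: Sequence[str] = DEFAULT_SMOOTHS,
    parametric_terms: Sequence[str] = DEFAULT_PARAMETRIC,
    group: str | None = "transmitter_id",
    df: int = 9,
    link: str = "inverse",
    alpha: Mapping[str, float] | None = None,
    select_alpha: bool = True,
    alpha_grid: Sequence[float] = (
        0.01, 0.1, 1.0, 10.0, 100.0, 1e3, 1e4, 1e5, 1e6, 1e7, 1e8
    ),
) -> GammResult:
    """Fit the Gamma visit-duration GAMM.

    Rows with missing covariates or non-positive durations are dropped (a
    count is reported via a warning when any are lost). The inverse link is
    attempted first; on failure the model is refit with a log link and the
    result flagged ``link_fallback=True``.
    """
    used = [response, *smooth_terms, *parametric_terms] + ([group] if group else [])
    data = visits.dropna(subset=[c for c in used if c in visits.columns])
    data = data[data[response] > 0]
    dropped = len(visits) - len(data)
    if dropped:
        warnings.warn(f"dropped {dropped} visits with missing covariates or zero duration")
    if len(data) < 50:
        raise ValueError(f"need >= 50 modelable visits, have {len(data)}")
    data = data.reset_index(drop=True)
    endog = data[response].to_numpy(dtype=float)
    smoother, term_names, _ = _build_smoothers(data, smooth_terms, group, df)
    exog = _design_parametric(data, parametric_terms)

    if alpha is not None:
        alpha_vec = [float(alpha.get(t, 1.0)) for t in term_names]
        select_alpha = False
    else:
        alpha_vec = [1.0] * len(term_names)

    def _try(link_name, avec):
        return _fit_once(endog, exog, smoother, avec, link_name)

    def _robust(link_name, avec):
        # a numerically degenerate fit often stabilizes under stronger
        # smoothing; try one boosted-penalty pass before giving up
        try:
            return _try(link_name, avec), avec
        except Exception:
            boosted = [a * 100.0 for a in avec]
            return _try(link_name, boosted), boosted

    link_used, fallback = link, False
    try:
        (model, res), alpha_vec = _robust(link_used, alpha_vec)
    except Exception:
        if link == "inverse":
            link_used, fallback = "log", True
            (model, res), alpha_vec = _robust(link_used, alpha_vec)
        else:
            raise
    if select_alpha:
        n = len(endog)
        best = _gcv(res, n)
        for _sweep in range(2):
            for i in range(len(alpha_vec)):
                for a in alpha_grid:
                    trial = list(alpha_vec)
                    trial[i] = a
                    try:
                        _, r = _try(link_used, trial)
                    except Exception:
                        continue
                    g = _gcv(r, n)
                    if g < best - 1e-10:
                        best, alpha_vec, res = g, trial, r
        (model, res), alpha_vec = _robust(link_used, alpha_vec)

    k_lin = exog.shape[1]
    edf = res.edf
    term_edf, term_p = {}, {}
    for i, t in enumerate(term_names):
        mask = smoother.mask[i]
        term_edf[t] = float(edf[k_lin + np.nonzero(mask)[0]].sum())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                term_p[t] = float(np.squeeze(res.test_significance(i).pvalue))
        except Exception:
            term_p[t] = np.nan
    par_tab = pd.DataFrame(
        {
            "coef": res.params[:k_lin],
            "se": res.bse[:k_lin],
            "t": res.tvalues[:k_lin],
            "p": res.pvalues[:k_lin],
        },
        index=list(exog.columns),
    )
    mu = np.asarray(res.fittedvalues, dtype=float)
    llf = float(res.family.loglike(endog, mu, scale=res.scale))
    return GammResult(
        results=res,
        smooth_terms=[t for t in term_names],
        parametric_terms=list(parametric_terms),
        term_edf=pd.Series(term_edf),
        term_pvalues=pd.Series(term_p),
        parametric_table=par_tab,
        link=link_used,
        link_fallback=fallback,
        alpha={t: a for t, a in zip(term_names, alpha_vec)},
        loglike=llf,
        edf_total=float(edf.sum()),
        n_obs=len(endog),
        group_term=group or "",
    )
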