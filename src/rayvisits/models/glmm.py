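"""Poisson GLMM with a single random intercept, fit by adaptive quadrature.

Model: counts y_ij ~ Poisson(mu_ij), log mu_ij = x_ij' beta + u_i, with a
per-group (transmitter) intercept u_i ~ N(0, sigma_u^2). Because the random
effect is a scalar per independent group, the marginal likelihood factors
into one-dimensional integrals, evaluated by adaptive Gauss-Hermite
quadrature centred at each group's posterior mode. Maximization is over
(beta, log sigma_u); Wald standard errors come from the numerical Hessian
of the marginal log-likelihood.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1


def build_design(
    data: pd.DataFrame,
    factors: Sequence[str],
    interaction: bool = True,
) -> tuple[np.ndarray, list[str], dict[str, list]]:
    """Full-interaction treatment-coded design matrix with an intercept.

    Empty factor-level combinations are tolerated (their columns are kept;
    rank issues only arise when a *margin* level is empty, which callers
    should prevent by dropping unused levels first).
    """
    levels = {f: sorted(pd.unique(data[f].astype(str))) for f in factors}
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    main = {}
    for f in factors:
        vals = data[f].astype(str).to_numpy()
        main[f] = []
        for lv in levels[f][1:]:
            cols.append((vals == lv).astype(float))
            names.append(f"{f}[{lv}]")
            main[f].append(len(cols) - 1)
    if interaction and len(factors) > 1:
        from itertools import combinations, product

        for k in range(2, len(factors) + 1):
            for combo in combinations(factors, k):
                idx_lists = [main[f] for f in combo]
                for idxs in product(*idx_lists):
                    col = np.ones(n)
                    for i in idxs:
                        col = col * cols[i]
                    if col.any():
                        cols.append(col)
                        names.append(":".join(names[i] for i in idxs))
    x = np.column_stack(cols)
    return x, names, levels


@dataclasses.dataclass
class GlmmResult:
    params: pd.Series
    bse: pd.Series
    sigma_u: float
    loglike: float
    converged: bool
    cov_params: pd.DataFrame
    n_obs: int
    n_groups: int
    levels: dict[str, list] | None = None
    factors: Sequence[str] | None = None

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index
        )

    @property
    def aic(self) -> float:
        k = len(self.params) + 1
        return 2 * k - 2 * self.loglike

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )


class PoissonGLMM:
    """Poisson mixed model with one random intercept per group."""

    def __init__(
        self,
        y: np.ndarray,
        x: np.ndarray,
        groups: np.ndarray,
        exog_names: Sequence[str] | None = None,
        n_quad: int = 15,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        codes, self.group_labels = pd.factorize(np.asarray(groups))
        order = np.argsort(codes, kind="stable")
        self._y = self.y[order]
        self._x = self.x[order]
        self._codes = codes[order]
        self._starts = np.searchsorted(self._codes, np.arange(len(self.group_labels) + 1))
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.x.shape[1])
        ]
        nodes, weights = special.roots_hermitegauss(n_quad) if hasattr(
            special, "roots_hermitegauss"
        ) else special.roots_hermite(n_quad)
        self._z = nodes
        self._logw = np.log(weights)

    # group-wise pieces -------------------------------------------------
    def _group_loglik(self, eta: np.ndarray, log_sigma: float) -> float:
        """Marginal log-likelihood, summed over groups, via adaptive GH."""
        sigma = np.exp(log_sigma)
        total = 0.0
        y, starts = self._y, self._starts
        log_fact = special.gammaln(y + 1.0)
        for g in range(len(starts) - 1):
            sl = slice(starts[g], starts[g + 1])
            yg, etag, lfg = y[sl], eta[sl], log_fact[sl]
            sy = yg.sum()
            # posterior mode of u: maximize sy*u - sum(exp(eta+u)) - u^2/(2s^2)
            u = 0.0
            for _ in range(50):
                e = np.exp(etag + u).sum()
                g1 = sy - e - u / sigma**2
                g2 = -e - 1.0 / sigma**2
                step = g1 / g2
                u -= step
                if abs(step) < 1e-10:
                    break
            tau = 1.0 / np.sqrt(np.exp(etag + u).sum() + 1.0 / sigma**2)
            uu = u + np.sqrt(2.0) * tau * self._z
            h = (
                sy * uu
                - np.exp(etag[:, None] + uu[None, :]).sum(axis=0)
                - 0.5 * uu**2 / sigma**2
            )
            const = (yg * etag - lfg).sum()
            lse = special.logsumexp(self._logw + self._z**2 + h)
            total += (
                const
                + lse
                + np.log(np.sqrt(2.0) * tau)
                - 0.5 * np.log(2 * np.pi * sigma**2)
            )
        return total

    def _negloglik(self, theta: np.ndarray) -> float:
        beta, log_sigma = theta[:-1], theta[-1]
        eta = self._x @ beta
        eta = np.clip(eta, -30, 30)
        return -self._group_loglik(eta, log_sigma)

    def fit(self, start_params: np.ndarray | None = None) -> GlmmResult:
        p = self.x.shape[1]
        if start_params is None:
            # Poisson GLM start via a few IRLS steps
            beta = np.zeros(p)
            beta[0] = np.log(self._y.mean() + 0.5)
            for _ in range(25):
                eta = np.clip(self._x @ beta, -30, 30)
                mu = np.exp(eta)
                w = mu
                z = eta + (self._y - mu) / np.maximum(mu, 1e-10)
                xtw = self._x.T * w
                try:
                    beta_new = np.linalg.solve(xtw @ self._x + 1e-8 * np.eye(p), xtw @ z)
                except np.linalg.LinAlgError:
                    break
                if np.max(np.abs(beta_new - beta)) < 1e-9:
                    beta = beta_new
                    break
                beta = beta_new
            start_params = np.r_[beta, np.log(0.5)]
        res = optimize.minimize(
            self._negloglik,
            start_params,
            method="BFGS",
            options={"gtol": 1e-6, "maxiter": 500},
        )
        theta = res.x
        # BFGS with numerical gradients often stops on "precision loss" at
        # the optimum; accept if the gradient is effectively zero.
        grad_ok = res.jac is not None and np.max(np.abs(res.jac)) < 1e-3 * (
            1.0 + abs(res.fun)
        )
        converged = bool(res.success or grad_ok)
        hess = approx_hess1(theta, self._negloglik)
        try:
            cov = np.linalg.inv(hess)
            bse = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        except np.linalg.LinAlgError:
            cov = np.full((len(theta), len(theta)), np.nan)
            bse = np.full(len(theta), np.nan)
        names = self.exog_names + ["log_sigma_u"]
        return GlmmResult(
            params=pd.Series(theta[:-1], index=self.exog_names),
            bse=pd.Series(bse[:-1], index=self.exog_names),
            sigma_u=float(np.exp(theta[-1])),
            loglike=float(-res.fun),
            converged=converged,
            cov_params=pd.DataFrame(cov, index=names, columns=names),
            n_obs=len(self.y),
            n_groups=len(self.group_labels),
        )


def fit_detection_glmm(
    cells: pd.DataFrame,
    response: str = "count",
    factors: Sequence[str] = ("diel", "receiver_id", "sex"),
    group: str = "transmitter_id",
    interaction: bool = True,
    n_quad: int = 15,
) -> GlmmResult:
    """Fit the detection-count model: Poisson GLMM, full factor interaction.

    ``cells`` holds one row per counting unit (per tag per local date per
    receiver per diel block) with the detection count, the factor columns
    and the grouping (transmitter) column. Factors with a single observed
    level are dropped from the design automatically.
    """
    data = cells.dropna(subset=[response, group, *factors])
    use = [f for f in factors if data[f].nunique() > 1]
    x, names, levels = build_design(data, use, interaction=interaction)
    model = PoissonGLMM(
        data[response].to_numpy(),
        x,
        data[group].to_numpy(),
        exog_names=names,
        n_quad=n_quad,
    )
    res = model.fit()
    res.levels = levels
    res.factors = use
    if not res.converged:
        # one retry from the previous optimum with a fresh BFGS run
        theta = np.r_[res.params.to_numpy(), np.log(max(res.sigma_u, 1e-3))]
        res2 = model.fit(start_params=theta)
        res2.levels, res2.factors = levels, use
        if res2.loglike >= res.loglike:
            res = res2
    return res
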