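"""All-subsets (dredge-style) model selection by AICc for the duration GAMM.

Every subset of the candidate smooth and parametric fixed terms is fit —
the intercept and the per-animal random intercept are always retained —
and models are ranked by small-sample corrected AIC. Smoothing weights
estimated once on the full model are reused across subsets, keeping the
search to one penalized fit per candidate.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .gamm import DEFAULT_PARAMETRIC, DEFAULT_SMOOTHS, aicc, fit_visit_gamm


def aicc_model_selection(
    visits: pd.DataFrame,
    response: str = "duration_min",
    candidate_smooths: Sequence[str] = DEFAULT_SMOOTHS,
    candidate_parametric: Sequence[str] = DEFAULT_PARAMETRIC,
    group: str | None = "transmitter_id",
    df: int = 9,
    link: str = "inverse",
    select_alpha: bool = True,
    **fit_kwargs,
) -> pd.DataFrame:
    """Rank all fixed-term subsets by AICc.

    Returns one row per candidate with its terms, effective df, restricted
    log-likelihood, AICc, delta to the best model and Akaike weight;
    non-converging subsets are kept with ``converged=False`` and excluded
    from the ranking. The best model is the AICc minimum; candidates within
    0.01 of it are treated as ties broken in favour of fewer terms.
    """
    user_alpha = fit_kwargs.pop("alpha", None)
    full = fit_visit_gamm(
        visits,
        response=response,
        smooth_terms=candidate_smooths,
        parametric_terms=candidate_parametric,
        group=group,
        df=df,
        link=link,
        alpha=user_alpha,
        select_alpha=select_alpha,
        **fit_kwargs,
    )
    alphas = full.alpha
    candidates = list(candidate_smooths) + list(candidate_parametric)
    rows = []
    for k in range(len(candidates) + 1):
        for subset in combinations(candidates, k):
            sm_terms = [t for t in candidate_smooths if t in subset]
            par_terms = [t for t in candidate_parametric if t in subset]
            try:
                fit = fit_visit_gamm(
                    visits,
                    response=response,
                    smooth_terms=sm_terms,
                    parametric_terms=par_terms,
                    group=group,
                    df=df,
                    link=full.link,
                    alpha=alphas,
                    **fit_kwargs,
                )
                rows.append(
                    {
                        "terms": "+".join(subset) if subset else "1",
                        "n_terms": len(subset),
                        "edf": fit.edf_total,
                        "loglike": fit.loglike,
                        "aicc": fit.aicc,
                        "link_fallback": fit.link_fallback,
                        "converged": True,
                    }
                )
            except Exception as err:  # non-convergence: recorded, not ranked
                rows.append(
                    {
                        "terms": "+".join(subset) if subset else "1",
                        "n_terms": len(subset),
                        "edf": np.nan,
                        "loglike": np.nan,
                        "aicc": np.inf,
                        "link_fallback": False,
                        "converged": False,
                        "error": str(err),
                    }
                )
    table = pd.DataFrame(rows)
    ok = table["converged"]
    best = table.loc[ok, "aicc"].min()
    table["delta_aicc"] = table["aicc"] - best
    rel = np.exp(-0.5 * table.loc[ok, "delta_aicc"])
    table.loc[ok, "weight"] = rel / rel.sum()
    table = table.sort_values(
        ["aicc", "n_terms"], kind="mergesort"
    ).reset_index(drop=True)
    return table


def select_best(table: pd.DataFrame, tie_tol: float = 0.01) -> pd.Series:
    """Best row: minimum AICc, ties within ``tie_tol`` broken by fewer terms."""
    ok = table[table["converged"]]
    best_aicc = ok["aicc"].min()
    ties = ok[ok["aicc"] - best_aicc < tie_tol]
    return ties.sort_values(["n_terms", "aicc"]).iloc[0]
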