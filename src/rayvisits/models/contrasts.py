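"""Estimated marginal means and Tukey-adjusted pairwise contrasts.

EMMs average the linear predictor (link scale) over a reference grid that
is balanced in the other factors; pairwise differences are tested with the
studentized-range adjustment, the standard "compare every pair of levels"
correction after an omnibus factor effect.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GlmmResult, build_design


def _emm_rows(result: GlmmResult, factor: str) -> tuple[pd.DataFrame, np.ndarray]:
    if not result.levels or factor not in result.levels:
        raise ValueError(f"factor {factor!r} not in fitted design")
    factors = list(result.factors)
    grids = [result.levels[f] for f in factors]
    grid = pd.DataFrame(list(product(*grids)), columns=factors)
    x, names, _ = build_design(grid, factors, interaction=True)
    # align columns with the fitted parameter vector
    name_to_col = {n: i for i, n in enumerate(names)}
    xa = np.zeros((len(grid), len(result.params)))
    for j, n in enumerate(result.params.index):
        if n in name_to_col:
            xa[:, j] = x[:, name_to_col[n]]
    lmat = []
    levels = result.levels[factor]
    for lv in levels:
        mask = (grid[factor] == lv).to_numpy()
        lmat.append(xa[mask].mean(axis=0))
    emm = pd.DataFrame({"level": levels})
    return emm, np.array(lmat)


def pairwise_contrasts(
    result: GlmmResult, factor: str, adjust: str = "tukey"
) -> pd.DataFrame:
    """All pairwise level contrasts of a fitted factor, on the link scale.

    Returns estimates, SEs, z statistics and Tukey (studentized-range)
    adjusted p-values. Levels whose EMM is inestimable (no parameters
    touch them — e.g. an entirely empty cell margin) are dropped with a
    note in the ``note`` column of the skipped pairs.
    """
    emm, lmat = _emm_rows(result, factor)
    vcov = result.cov_params.iloc[:-1, :-1].to_numpy()  # drop log_sigma row/col
    est = lmat @ result.params.to_numpy()
    k = len(emm)
    rows = []
    for i, j in combinations(range(k), 2):
        d = lmat[i] - lmat[j]
        var = float(d @ vcov @ d)
        if not np.isfinite(var) or var <= 0:
            rows.append(
                {
                    "contrast": f"{emm['level'][i]} - {emm['level'][j]}",
                    "estimate": np.nan,
                    "se": np.nan,
                    "z": np.nan,
                    "p_adjusted": np.nan,
                    "note": "inestimable",
                }
            )
            continue
        se = np.sqrt(var)
        z = (est[i] - est[j]) / se
        if adjust == "tukey":
            # studentized range with df -> infinity (Wald/z asymptotics)
            p = stats.studentized_range.sf(np.abs(z) * np.sqrt(2.0), k, 1e6)
        elif adjust == "none":
            p = 2 * stats.norm.sf(np.abs(z))
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append(
            {
                "contrast": f"{emm['level'][i]} - {emm['level'][j]}",
                "estimate": est[i] - est[j],
                "se": se,
                "z": z,
                "p_adjusted": float(np.clip(p, 0.0, 1.0)),
                "note": "",
            }
        )
    return pd.DataFrame(rows)


def diel_within_receiver_contrasts(result: GlmmResult) -> pd.DataFrame:
    """Day vs night contrast within each receiver (simple effects)."""
    factors = list(result.factors)
    if "diel" not in factors or "receiver_id" not in factors:
        raise ValueError("model must include diel and receiver_id")
    grids = [result.levels[f] for f in factors]
    grid = pd.DataFrame(list(product(*grids)), columns=factors)
    x, names, _ = build_design(grid, factors, interaction=True)
    name_to_col = {n: i for i, n in enumerate(names)}
    xa = np.zeros((len(grid), len(result.params)))
    for j, n in enumerate(result.params.index):
        if n in name_to_col:
            xa[:, j] = x[:, name_to_col[n]]
    vcov = result.cov_params.iloc[:-1, :-1].to_numpy()
    rows = []
    n_tests = len(result.levels["receiver_id"])
    for rid in result.levels["receiver_id"]:
        m_day = ((grid["receiver_id"] == rid) & (grid["diel"] == "day")).to_numpy()
        m_night = ((grid["receiver_id"] == rid) & (grid["diel"] == "night")).to_numpy()
        d = xa[m_day].mean(axis=0) - xa[m_night].mean(axis=0)
        var = float(d @ vcov @ d)
        se = np.sqrt(var) if var > 0 else np.nan
        z = float(d @ result.params.to_numpy()) / se if se else np.nan
        p = stats.studentized_range.sf(abs(z) * np.sqrt(2.0), 2 * n_tests, 1e6)
        rows.append(
            {"receiver_id": rid, "estimate": float(d @ result.params.to_numpy()),
             "se": se, "z": z, "p_adjusted": float(np.clip(p, 0, 1))}
        )
    return pd.DataFrame(rows)
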