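"""Collinearity screening of model covariates (correlation + VIF)."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools import add_constant


@dataclasses.dataclass
class CollinearityReport:
    correlation: pd.DataFrame
    vif: pd.Series  # VIFs for the retained covariates (final pass)
    dropped: list[str]
    flags: dict[str, str]


def collinearity_screen(
    covariates: pd.DataFrame,
    threshold: float = 3.0,
    keep_order: Sequence[str] | None = None,
) -> CollinearityReport:
    """Pairwise Pearson correlations and VIFs, with an iterative drop rule.

    While any variance inflation factor exceeds ``threshold``, the
    last-listed offending covariate is dropped (so the first-listed member
    of a collinear pair is retained). Constant columns have undefined VIF;
    they are flagged and excluded from the auxiliary fits. Near-duplicate
    columns produce effectively infinite VIFs and are flagged as such.
    """
    if covariates.shape[1] < 2 or len(covariates) < 10:
        raise ValueError("need >= 2 numeric covariates and >= 10 rows")
    cols = list(keep_order or covariates.columns)
    data = covariates[cols].astype(float).dropna()
    corr = data.corr()

    flags: dict[str, str] = {}
    active = []
    for c in cols:
        if np.isclose(data[c].std(ddof=0), 0.0):
            flags[c] = "constant: VIF undefined"
        else:
            active.append(c)

    dropped: list[str] = []
    while True:
        x = add_constant(data[active].to_numpy(), has_constant="add")
        with np.errstate(divide="ignore"):
            vifs = np.array(
                [variance_inflation_factor(x, i + 1) for i in range(len(active))]
            )
        for name, v in zip(active, vifs):
            if not np.isfinite(v) or v > 1e6:
                flags[name] = "near-duplicate: VIF effectively infinite"
        offenders = [i for i, v in enumerate(vifs) if (not np.isfinite(v)) or v > threshold]
        if not offenders:
            break
        victim = active[max(offenders)]  # last-listed offender goes
        dropped.append(victim)
        active.remove(victim)
        if len(active) < 2:
            break

    if active:
        x = add_constant(data[active].to_numpy(), has_constant="add")
        with np.errstate(divide="ignore"):
            vifs = np.array(
                [variance_inflation_factor(x, i + 1) for i in range(len(active))]
            )
        vif = pd.Series(vifs, index=active, name="VIF")
    else:
        vif = pd.Series(dtype=float, name="VIF")
    return CollinearityReport(correlation=corr, vif=vif, dropped=dropped, flags=flags)
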