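"""Detection and visit summary tables.

Mirrors the standard reporting shapes for array-based telemetry studies:
per-species x per-receiver detection counts with proportions, diel split
means and totals, visit-duration summaries with margins, visit-time
proportions by location group, and long-visit counts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


def _sem(x: np.ndarray) -> float:
    """Standard error of the mean; 0 by convention for a single value."""
    if len(x) <= 1:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def summarize_detections(
    det: pd.DataFrame,
    tags: pd.DataFrame,
    orphan: str = "raise",
) -> pd.DataFrame:
    """Detection counts per (species, receiver) with within-species proportions.

    ``tags`` maps transmitter_id -> species. Returns tidy rows with
    ``n_detections``, ``prop_of_species_total`` (fraction of that species'
    total) and ``unique_tags``; plus one ``Total`` margin row per species.
    """
    merged = det.merge(
        tags[["transmitter_id", "species"]], on="transmitter_id", how="left"
    )
    if merged["species"].isna().any():
        missing = sorted(merged.loc[merged["species"].isna(), "transmitter_id"].unique())
        msg = f"detections from transmitters with no deployment record: {missing}"
        if orphan == "raise":
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
        merged = merged.dropna(subset=["species"])
    cells = (
        merged.groupby(["species", "receiver_id"], observed=True)
        .agg(
            n_detections=("timestamp", "size"),
            unique_tags=("transmitter_id", "nunique"),
        )
        .reset_index()
    )
    totals = (
        merged.groupby("species", observed=True)
        .agg(
            n_detections=("timestamp", "size"),
            unique_tags=("transmitter_id", "nunique"),
        )
        .reset_index()
        .assign(receiver_id="Total")
    )
    out = pd.concat([cells, totals], ignore_index=True)
    sp_tot = out.loc[out["receiver_id"] == "Total"].set_index("species")["n_detections"]
    out["prop_of_species_total"] = out.apply(
        lambda r: r["n_detections"] / sp_tot[r["species"]], axis=1
    )
    return out.sort_values(["species", "receiver_id"]).reset_index(drop=True)


def species_proportions(counts: pd.DataFrame, value_col: str = "n_detections") -> pd.Series:
    """Within-species proportions from a tidy (species, receiver, count) table.

    Margin rows (receiver_id == "Total") are ignored if present; proportions
    are cell / species total.
    """
    cells = counts[counts["receiver_id"] != "Total"]
    totals = cells.groupby("species")[value_col].transform("sum")
    return cells[value_col] / totals


def group_share_percent(
    counts: pd.DataFrame,
    receivers_in_group: Sequence[str],
    species: str | Sequence[str],
    value_col: str = "n_detections",
) -> float:
    """Percent of a species' (or pooled species') total in a receiver group.

    Reported to one decimal, rounding half away from zero.
    """
    if isinstance(species, str):
        species = [species]
    cells = counts[(counts["receiver_id"] != "Total") & counts["species"].isin(species)]
    total = cells[value_col].sum()
    share = cells.loc[cells["receiver_id"].isin(receivers_in_group), value_col].sum()
    return round_half_away(100.0 * share / total, 1)


def summarize_diel(det_annotated: pd.DataFrame, tags: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SE and total detections per (species, receiver, diel).

    The mean is over per-tag per-local-date detection counts within the
    cell (each tag-date with at least one detection contributes one count);
    totals are raw detection counts.
    """
    merged = det_annotated.merge(
        tags[["transmitter_id", "species"]], on="transmitter_id", how="left"
    )
    per_tag_day = (
        merged.groupby(
            ["species", "receiver_id", "diel", "transmitter_id", "date_local"],
            observed=True,
        )
        .size()
        .rename("count")
        .reset_index()
    )
    out = (
        per_tag_day.groupby(["species", "receiver_id", "diel"], observed=True)["count"]
        .agg(
            mean="mean",
            se=lambda x: _sem(x.to_numpy()),
            total="sum",
        )
        .reset_index()
    )
    return out


def summarize_visits(visits: pd.DataFrame, tags: pd.DataFrame) -> pd.DataFrame:
    """Visit-duration summary per (species, receiver) with species margins.

    Rows carry unique tags, min/max/mean duration, SE of the mean (0 by
    convention when N = 1) the number of visits and the summed visit time.
    """
    merged = visits.merge(
        tags[["transmitter_id", "species"]], on="transmitter_id", how="left"
    )

    def _agg(grp: pd.DataFrame) -> pd.Series:
        d = grp["duration_min"].to_numpy(dtype=float)
        return pd.Series(
            {
                "unique_tags": grp["transmitter_id"].nunique(),
                "min_min": d.min(),
                "max_min": d.max(),
                "mean_min": d.mean(),
                "se_min": _sem(d),
                "n_visits": len(d),
                "total_time_min": d.sum(),
            }
        )

    cells = (
        merged.groupby(["species", "receiver_id"], observed=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    margins = (
        merged.groupby("species", observed=True)
        .apply(_agg, include_groups=False)
        .reset_index()
        .assign(receiver_id="Total")
    )
    out = pd.concat([cells, margins], ignore_index=True)
    for col in ("unique_tags", "n_visits"):
        out[col] = out[col].astype(int)
    return out.sort_values(["species", "receiver_id"]).reset_index(drop=True)


def proportion_visit_time(
    visit_summary: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Percent of each species' total visit time per receiver group.

    ``grouping`` maps receiver_id -> group label and must cover every
    non-margin receiver in the summary. Percentages are reported to one
    decimal (half away from zero) and sum to ~100 per species.
    """
    cells = visit_summary[visit_summary["receiver_id"] != "Total"].copy()
    missing = set(cells["receiver_id"]) - set(grouping)
    if missing:
        raise ValueError(f"receivers not covered by grouping: {sorted(missing)}")
    cells["group"] = cells["receiver_id"].map(grouping)
    grp = (
        cells.groupby(["species", "group"], observed=True)["total_time_min"]
        .sum()
        .reset_index()
    )
    totals = grp.groupby("species")["total_time_min"].transform("sum")
    grp["percent"] = round_half_away(100.0 * grp["total_time_min"] / totals, 1)
    return grp


def count_long_visits(
    visits_classified: pd.DataFrame,
    tags: pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count long visits per (species, group); strict duration > threshold."""
    merged = visits_classified.merge(
        tags[["transmitter_id", "species"]], on="transmitter_id", how="left"
    )
    merged["group"] = (
        merged["receiver_id"].map(grouping) if grouping else merged["receiver_id"]
    )
    out = (
        merged[merged["visit_class"] == "long"]
        .groupby(["species", "group"], observed=True)
        .size()
        .rename("n_long_visits")
        .reset_index()
    )
    return out
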