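"""Island-scale aggregation: area-weighted stratified estimation,
island quality filters, reef-area pooling, and covariate assembly.

Sites are stratified by depth bin within the forereef zone; island means and
variances are computed per stratum first and then combined with weights
proportional to stratum hardbottom area:

    mean = sum_h w_h * ybar_h,     w_h = area_h / sum(area)
    var  = sum_h w_h^2 * s_h^2 / n_h

Strata with a single site contribute zero variance (with a warning). No
finite-population correction is applied.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .survey import TROPHIC_GROUPS

__all__ = [
    "stratified_island_mean",
    "aggregate_islands",
    "filter_islands",
    "pool_reef_areas",
    "build_covariates",
    "build_island_table",
]

#: Island-table column names for the model predictors.
PREDICTOR_COLUMNS = ("AT", "CHL", "CX", "HC", "HDIST", "HUM", "SSTL", "WV")


def stratified_island_mean(
    values: Sequence[float] | pd.Series,
    strata: Sequence | pd.Series,
    areas: Mapping[str, float],
) -> tuple[float, float]:
    """Area-weighted stratified mean and variance-of-the-mean.

    Parameters
    ----------
    values : site-level values.
    strata : stratum label per site (parallel to ``values``).
    areas : stratum -> habitat area; only strata that contain sites need
        appear, and each such stratum must have positive area.

    Returns
    -------
    (mean, variance_of_mean)

    Raises
    ------
    ValueError
        If there are no sites, or a sampled stratum has no positive area.
    """
    vals = np.asarray(values, dtype=float)
    labels = pd.Series(list(strata))
    if len(vals) == 0:
        raise ValueError("stratified mean of zero sites")
    if len(vals) != len(labels):
        raise ValueError("values and strata must be the same length")

    present = labels.unique()
    for h in present:
        if areas.get(h, 0.0) <= 0:
            raise ValueError(f"stratum {h!r} has sites but no positive area")
    total_area = sum(areas[h] for h in present)

    mean = 0.0
    var = 0.0
    singletons = []
    for h in present:
        sel = vals[(labels == h).to_numpy()]
        w = areas[h] / total_area
        mean += w * sel.mean()
        n_h = len(sel)
        if n_h > 1:
            var += w**2 * sel.var(ddof=1) / n_h
        else:
            singletons.append(h)
    if singletons:
        warnings.warn(
            f"strata {singletons} have a single site; they contribute zero "
            "variance",
            stacklevel=2,
        )
    return float(mean), float(var)


def aggregate_islands(
    site_table: pd.DataFrame,
    strata_areas: pd.DataFrame,
) -> pd.DataFrame:
    """Island-scale mean and SE of biomass (per trophic group and total)
    and of benthic covariates, via area-weighted stratified estimation.

    Parameters
    ----------
    site_table : one row per site with ``site_id, island_id, stratum``,
        biomass columns (trophic groups + ``total``) and, if present,
        ``hard_coral_pct`` and ``complexity_m``.
    strata_areas : ``island_id, stratum, area_ha``.

    Returns
    -------
    DataFrame with one row per island: ``n_sites``, ``mean_<col>`` and
    ``se_<col>`` for every aggregated column, and ``cv_total`` = SE/mean of
    total biomass.
    """
    value_cols = [c for c in list(TROPHIC_GROUPS) + ["total"] if c in site_table]
    for extra in ("hard_coral_pct", "complexity_m"):
        if extra in site_table:
            value_cols.append(extra)

    rows = []
    for island, grp in site_table.groupby("island_id", sort=True):
        areas = (
            strata_areas.loc[strata_areas["island_id"] == island]
            .set_index("stratum")["area_ha"]
            .to_dict()
        )
        if not areas:
            raise ValueError(f"island {island!r} has sites but no strata areas")
        row: dict = {"island_id": island, "n_sites": len(grp)}
        for col in value_cols:
            m, v = stratified_island_mean(grp[col], grp["stratum"], areas)
            row[f"mean_{col}"] = m
            row[f"se_{col}"] = float(np.sqrt(v))
        row["cv_total"] = (
            row["se_total"] / row["mean_total"] if row.get("mean_total") else np.inf
        )
        rows.append(row)
    return pd.DataFrame(rows)


def filter_islands(
    summary: pd.DataFrame,
    min_sites: int = 12,
    max_cv: float = 0.40,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop islands with too few sites or too-imprecise total biomass.

    CV is SE/mean of total biomass. Defaults (``min_sites=12``,
    ``max_cv=0.40``) drop reef areas surveyed at only 8 sites or with CV
    of 47% and above while retaining every area with >= 12 sites and
    CV <= 35%.

    Returns
    -------
    (retained, excluded)
        ``excluded`` carries a ``reason`` column.

    Raises
    ------
    ValueError
        If every island would be dropped.
    """
    too_few = summary["n_sites"] < min_sites
    too_noisy = summary["cv_total"] > max_cv
    reasons = []
    for few, noisy in zip(too_few, too_noisy):
        r = []
        if few:
            r.append(f"n_sites < {min_sites}")
        if noisy:
            r.append(f"cv_total > {max_cv}")
        reasons.append("; ".join(r))
    excluded = summary.loc[too_few | too_noisy].copy()
    excluded["reason"] = [r for r in reasons if r]
    retained = summary.loc[~(too_few | too_noisy)].copy()
    if retained.empty:
        raise ValueError("island filter removed every island")
    return retained, excluded


def pool_reef_areas(
    islands: pd.DataFrame,
    pooling: Mapping[str, Sequence[str]],
    sites: pd.DataFrame | None = None,
    strata_areas: pd.DataFrame | None = None,
):
    """Pool groups of adjacent islands into single reporting units.

    Covariate rows of pooled members are combined as unweighted means of
    the member values (matching the published convention for the pooled
    Sarigan-Guguan-Alamagan row). When ``sites``/``strata_areas`` are given,
    their ``island_id`` labels are rewritten to the pooled unit and member
    stratum areas are summed, so downstream stratified estimation runs on
    the concatenated site set.

    Parameters
    ----------
    pooling : mapping pooled-unit name -> list of member island names.

    Returns
    -------
    islands-only call: pooled islands DataFrame.
    Otherwise: ``(islands, sites, strata_areas)`` tuple.
    """
    islands = islands.copy()
    name_col = "island" if "island" in islands.columns else "island_id"
    for unit, members in pooling.items():
        missing = set(members) - set(islands[name_col])
        if missing:
            raise ValueError(f"pooled unit {unit!r} missing members: {sorted(missing)}")
        sel = islands[name_col].isin(members)
        num = islands.loc[sel].select_dtypes("number").mean()
        row = islands.loc[sel].iloc[0].copy()
        row[num.index] = num
        row[name_col] = unit
        islands = pd.concat(
            [islands.loc[~sel], row.to_frame().T], ignore_index=True
        )
    if sites is None and strata_areas is None:
        return islands

    def _relabel(df):
        df = df.copy()
        for unit, members in pooling.items():
            df.loc[df["island_id"].isin(members), "island_id"] = unit
        return df

    sites_out = _relabel(sites) if sites is not None else None
    if strata_areas is not None:
        sa = _relabel(strata_areas)
        sa = sa.groupby(["island_id", "stratum"], as_index=False)["area_ha"].sum()
    else:
        sa = None
    return islands, sites_out, sa


def build_covariates(islands: pd.DataFrame) -> pd.DataFrame:
    """Derive model covariates from island metadata.

    HUM and HDIST are square-root-transformed population densities
    (residents, resp. distant population, per hectare of forereef); AT is
    the atoll flag as 0/1. Oceanographic columns are renamed to their
    predictor labels.

    Raises
    ------
    ValueError
        On nonpositive forereef area or negative population.
    """
    out = islands.copy()
    if (out["forereef_ha"] <= 0).any():
        bad = out.loc[out["forereef_ha"] <= 0, out.columns[0]].tolist()
        raise ValueError(f"nonpositive forereef area for {bad}")
    for col in ("pop", "distant_pop"):
        if (out[col] < 0).any():
            raise ValueError(f"negative {col}")
    out["HUM"] = np.sqrt(out["pop"] / out["forereef_ha"])
    out["HDIST"] = np.sqrt(out["distant_pop"] / out["forereef_ha"])
    out["AT"] = out["atoll"].astype(int)
    out = out.rename(columns={"chl": "CHL", "wv": "WV", "sstl": "SSTL"})
    return out


def build_island_table(
    summary: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Join aggregated island responses to their covariates.

    ``summary`` comes from :func:`aggregate_islands` (possibly filtered);
    ``covariates`` from :func:`build_covariates`. Benthic island means are
    exposed as HC (% hard coral) and CX (mean substrate height, m).
    """
    cov = covariates.copy()
    if "island_id" not in cov.columns:
        cov = cov.rename(columns={"island": "island_id"})
    elif "island" in cov.columns:
        cov = cov.drop(columns="island")
    table = summary.merge(cov, on="island_id", how="left", validate="1:1")
    if "mean_hard_coral_pct" in table:
        table["HC"] = table["mean_hard_coral_pct"]
    if "mean_complexity_m" in table:
        table["CX"] = table["mean_complexity_m"]
    return table
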