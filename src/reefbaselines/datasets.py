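"""Packaged island covariate table.

The table ships with the package as a plain CSV: one row per reef area
(37 rows — three small adjacent Northern Mariana islands are already pooled
into the single ``Sarigan-Guguan-Alamagan`` reporting unit), with geographic
position, atoll flag, forereef area in hectares, resident and distant (within
200 km, non-resident) human population counts, and long-term oceanographic
means (CHL in mg m^-3, WV in kW m^-1, SSTL in degrees C).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_island_covariates", "covariate_ranges"]

_DATA_PACKAGE = "reefbaselines.data"
_ISLANDS_CSV = "island_covariates.csv"


def load_island_covariates() -> pd.DataFrame:
    """Load the packaged island covariate table.

    Returns
    -------
    pandas.DataFrame
        Columns ``region, island, lat, lon, atoll, forereef_ha, pop,
        distant_pop, chl, wv, sstl``; one row per reef area. Missing
        populations are encoded as 0 (uninhabited).
    """
    with resources.files(_DATA_PACKAGE).joinpath(_ISLANDS_CSV).open() as fh:
        df = pd.read_csv(fh)
    df["atoll"] = df["atoll"].astype(int)
    return df


def covariate_ranges(df: pd.DataFrame | None = None) -> dict[str, tuple[float, float]]:
    """Observed (min, max) per oceanographic covariate, for simulation defaults."""
    if df is None:
        df = load_island_covariates()
    return {
        "CHL": (float(df["chl"].min()), float(df["chl"].max())),
        "WV": (float(df["wv"].min()), float(df["wv"].max())),
        "SSTL": (float(df["sstl"].min()), float(df["sstl"].max())),
    }
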