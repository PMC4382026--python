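"""Site-level processing of stationary point count survey records.

Converts raw fish observation records (taxon, count, total length) into
site-level biomass density by trophic group, applying the analysis
exclusions (sharks and jacks; strictly protected MPA sites) and the
structural-complexity protocol calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TROPHIC_GROUPS",
    "CYLINDER_DIAMETER_M",
    "cylinder_area_m2",
    "fish_mass",
    "apply_exclusions",
    "site_biomass",
    "calibrate_complexity",
    "ComplexityCalibration",
]

#: Trophic groups used throughout: herbivores+detritivores; omnivores and
#: benthic invertivores; planktivores; piscivores (sharks/jacks excluded).
TROPHIC_GROUPS = ("primary", "secondary", "planktivore", "piscivore")

#: Diameter of one survey cylinder (paired divers, two adjacent cylinders).
CYLINDER_DIAMETER_M = 15.0


def cylinder_area_m2(diameter_m: float = CYLINDER_DIAMETER_M) -> float:
    """Plan area of one survey cylinder in m^2."""
    return math.pi * (diameter_m / 2.0) ** 2


def fish_mass(lw_a, lw_b, length_cm):
    """Length–weight allometry ``W = a * L**b`` (L in cm, W in grams).

    Accepts scalars or array-likes (broadcast elementwise).

    Raises
    ------
    ValueError
        If any of ``lw_a``, ``lw_b`` or ``length_cm`` is not strictly positive.
    """
    a = np.asarray(lw_a, dtype=float)
    b = np.asarray(lw_b, dtype=float)
    length = np.asarray(length_cm, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0) or np.any(length <= 0):
        raise ValueError("fish_mass requires a > 0, b > 0 and length > 0")
    out = a * length**b
    if out.ndim == 0:
        return float(out)
    return out


def apply_exclusions(
    records: pd.DataFrame,
    species: pd.DataFrame,
    sites: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Drop shark/jack records and strictly protected MPA sites.

    Parameters
    ----------
    records : DataFrame with ``site_id, cylinder_id, taxon_id, count, length_cm``.
    species : DataFrame with ``taxon_id, lw_a, lw_b, trophic_group, shark_or_jack``.
    sites : DataFrame with at least ``site_id``; an ``mpa_strict`` boolean
        column marks sites inside strictly enforced no-fishing areas.

    Returns
    -------
    (records, sites, log)
        Filtered copies plus a log dict with counts removed per rule.

    Raises
    ------
    KeyError
        If any record taxon is missing from the species table.
    """
    unknown = set(records["taxon_id"]) - set(species["taxon_id"])
    if unknown:
        raise KeyError(f"records reference unknown taxa: {sorted(unknown)}")

    flagged_taxa = set(species.loc[species["shark_or_jack"].astype(bool), "taxon_id"])
    is_sj = records["taxon_id"].isin(flagged_taxa)

    if "mpa_strict" in sites.columns:
        mpa_mask = sites["mpa_strict"].astype(bool)
    else:
        mpa_mask = pd.Series(False, index=sites.index)
    mpa_sites = set(sites.loc[mpa_mask, "site_id"])

    rec_out = records.loc[~is_sj & ~records["site_id"].isin(mpa_sites)].copy()
    sites_out = sites.loc[~mpa_mask].copy()
    log = {
        "shark_jack_records_removed": int(is_sj.sum()),
        "mpa_sites_removed": int(mpa_mask.sum()),
        "records_removed_at_mpa_sites": int(
            (records["site_id"].isin(mpa_sites) & ~is_sj).sum()
        ),
    }
    return rec_out, sites_out, log


def site_biomass(
    records: pd.DataFrame,
    species: pd.DataFrame,
    sites: pd.DataFrame | None = None,
    cylinder_diameter_m: float = CYLINDER_DIAMETER_M,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-site biomass density (g m^-2) by trophic group.

    Each cylinder's density is the summed mass of its records divided by the
    cylinder plan area; the site value is the mean of its cylinder densities
    (two cylinders per site by design — cylinders with no records count as
    zero). ``total`` is the sum over trophic groups.

    Parameters
    ----------
    sites : optional site table; if given, defines the full site list (sites
        with no records get zero biomass) and may carry an ``n_cylinders``
        column (default 2). Sites with a single usable cylinder are kept with
        a warning, or dropped when ``strict=True``.

    Raises
    ------
    ValueError
        If a site has zero cylinders, or on unknown taxa.
    """
    unknown = set(records["taxon_id"]) - set(species["taxon_id"])
    if unknown:
        raise KeyError(f"records reference unknown taxa: {sorted(unknown)}")

    area = cylinder_area_m2(cylinder_diameter_m)

    if sites is not None:
        site_ids = pd.Index(sites["site_id"].unique(), name="site_id")
        if "n_cylinders" in sites.columns:
            n_cyl = sites.set_index("site_id")["n_cylinders"].astype(int)
        else:
            n_cyl = pd.Series(2, index=site_ids)
    else:
        site_ids = pd.Index(records["site_id"].unique(), name="site_id")
        n_cyl = pd.Series(2, index=site_ids)

    if (n_cyl <= 0).any():
        bad = list(n_cyl.index[n_cyl <= 0])
        raise ValueError(f"sites with zero cylinders: {bad}")
    partial = n_cyl.index[n_cyl == 1]
    if len(partial):
        if strict:
            keep = n_cyl.index[n_cyl >= 2]
            site_ids = site_ids.intersection(keep)
            n_cyl = n_cyl.loc[site_ids]
        else:
            warnings.warn(
                f"{len(partial)} site(s) have a single usable cylinder; kept",
                stacklevel=2,
            )

    merged = records.merge(
        species[["taxon_id", "lw_a", "lw_b", "trophic_group"]],
        on="taxon_id",
        how="left",
    )
    merged = merged[merged["site_id"].isin(site_ids)]
    mass = fish_mass(merged["lw_a"], merged["lw_b"], merged["length_cm"])
    merged = merged.assign(mass_g=mass * merged["count"].to_numpy())

    # mass per site x group, pooled over cylinders, then averaged per cylinder
    per_site = (
        merged.pivot_table(
            index="site_id",
            columns="trophic_group",
            values="mass_g",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(index=site_ids, columns=list(TROPHIC_GROUPS), fill_value=0.0)
        .astype(float)
    )
    dens = per_site.div(area).div(n_cyl.reindex(site_ids), axis=0)
    dens["total"] = dens[list(TROPHIC_GROUPS)].sum(axis=1)
    return dens.reset_index()


@dataclass(frozen=True)
class ComplexityCalibration:
    """OLS mapping from the categorical (1–5) complexity protocol to
    measured mean vertical substrate height (m)."""

    slope: float
    intercept: float
    r_squared: float

    def convert(self, value: float, protocol: str = "categorical") -> float:
        """Predicted height for a categorical score; measured heights pass
        through unchanged."""
        if protocol == "measured":
            return float(value)
        return self.intercept + self.slope * float(value)


def calibrate_complexity(pairs: pd.DataFrame) -> ComplexityCalibration:
    """Fit the categorical→height conversion by ordinary least squares.

    Parameters
    ----------
    pairs : DataFrame with columns ``category`` (1–5 scores) and
        ``height_m`` (measured mean vertical relief) from sites surveyed
        under both protocols.

    Raises
    ------
    ValueError
        With fewer than 3 pairs or fewer than 2 distinct category values.
    """
    if len(pairs) < 3:
        raise ValueError("complexity calibration needs at least 3 paired sites")
    x = pairs["category"].to_numpy(dtype=float)
    y = pairs["height_m"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate design: all category values identical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ComplexityCalibration(float(slope), float(intercept), r2)
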