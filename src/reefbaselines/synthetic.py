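"""Synthetic survey-data generator with known ground truth.

Emulates the full data hierarchy the analysis assumes — islands with
oceanographic/human covariates, depth strata, survey sites, and paired
15 m cylinder fish records — so that the whole pipeline can be exercised and
its estimates checked against a known truth.

Island expected biomass is log-linear in configurable covariate effect
functions; the default human effect is a negative-exponential multiplier in
the square-root of population density, ``exp(-lambda * sqrt(density))``,
with lambda chosen so that a density of 40 residents per hectare of forereef
depletes ~75% of total biomass (steep decline at low density, gradual
beyond). Site totals are gamma-distributed around the island expectation;
fish records are drawn to reproduce each site total exactly through the
length-weight allometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .survey import TROPHIC_GROUPS, cylinder_area_m2

__all__ = [
    "ConfigurationError",
    "EffectSpec",
    "SimulationConfig",
    "simulate_species_table",
    "simulate_islands",
    "simulate_surveys",
    "simulate_calibration_pairs",
    "simulate_dataset",
    "write_dataset",
    "HUMAN_DECAY_RATE",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


#: lambda with exp(-lambda * sqrt(40)) = 0.25: ~75% decline at 40 residents/ha.
HUMAN_DECAY_RATE = math.log(4.0) / math.sqrt(40.0)

#: Observed covariate ranges used as simulation defaults.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "CHL": (0.03, 0.21),
    "WV": (15.5, 46.1),
    "SSTL": (19.0, 27.9),
    "HC": (3.0, 38.0),
    "CX": (0.29, 0.92),
}

#: Baseline (all effects zero) expected biomass per trophic group, g m^-2.
DEFAULT_BASE_BIOMASS: dict[str, float] = {
    "primary": 17.0,
    "secondary": 8.0,
    "planktivore": 7.5,
    "piscivore": 8.0,
}


@dataclass(frozen=True)
class EffectSpec:
    """One covariate's contribution to island log-biomass.

    kind:
      ``linear``      amplitude * (x - min) / (max - min)
      ``saturating``  amplitude * (1 - exp(-3 (x - min)/(max - min)))
      ``decay``       amplitude * x — for the sqrt-density human covariates,
                      where a negative amplitude yields the
                      steep-then-gradual decline in density space.
    """

    kind: str
    amplitude: float

    def __call__(self, x, lo: float, hi: float):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.amplitude * (x - lo) / (hi - lo)
        if self.kind == "saturating":
            return self.amplitude * (1.0 - np.exp(-3.0 * (x - lo) / (hi - lo)))
        if self.kind == "decay":
            return self.amplitude * x
        raise ConfigurationError(f"unknown effect kind {self.kind!r}")


def _default_effects() -> dict[str, EffectSpec]:
    return {
        "CHL": EffectSpec("linear", 0.8),
        "HUM": EffectSpec("decay", -HUMAN_DECAY_RATE),
        "HDIST": EffectSpec("decay", -0.05),
    }


def _default_strata() -> list[tuple[str, float, float]]:
    return [("shallow", 0.25, 0.25), ("mid", 0.50, 0.50), ("deep", 0.25, 0.25)]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic survey generator.

    strata_spec entries are ``(label, area_fraction, site_allocation_fraction)``;
    both fraction columns must sum to 1. ``dispersion`` is the gamma shape of
    site-level totals (larger = less site noise). ``sites_per_island`` may be
    an int or an inclusive (low, high) range.
    """

    n_islands: int = 40
    sites_per_island: int | tuple[int, int] = 30
    strata_spec: list[tuple[str, float, float]] = field(
        default_factory=_default_strata
    )
    covariate_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    true_effects: dict[str, EffectSpec] = field(default_factory=_default_effects)
    base_biomass: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_BIOMASS)
    )
    dispersion: float = 4.0
    species_pool_size: int = 24
    p_inhabited: float = 0.45
    p_distant: float = 0.35
    p_atoll: float = 0.27
    mpa_fraction: float = 0.0
    shark_biomass_gm2: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_islands < 1:
            raise ConfigurationError("n_islands must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion (gamma shape) must be > 0")
        if not self.strata_spec:
            raise ConfigurationError("at least one stratum required")
        areas = sum(s[1] for s in self.strata_spec)
        allocs = sum(s[2] for s in self.strata_spec)
        if abs(areas - 1.0) > 1e-9 or abs(allocs - 1.0) > 1e-9:
            raise ConfigurationError("strata area/allocation fractions must sum to 1")
        for name, (lo, hi) in self.covariate_ranges.items():
            if not lo < hi:
                raise ConfigurationError(f"covariate {name}: need min < max")
        for g in TROPHIC_GROUPS:
            if self.base_biomass.get(g, 0.0) <= 0:
                raise ConfigurationError(f"base biomass for {g!r} must be > 0")
        if isinstance(self.sites_per_island, tuple):
            lo, hi = self.sites_per_island
            if not (1 <= lo <= hi):
                raise ConfigurationError("invalid sites_per_island range")
        elif self.sites_per_island < 1:
            raise ConfigurationError("sites_per_island must be >= 1")


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def simulate_species_table(config: SimulationConfig) -> pd.DataFrame:
    """Species traits: length-weight a/b, trophic group, shark/jack flag.

    Groups are assigned round-robin so all four are always represented; a
    small fraction of piscivores is flagged shark-or-jack (never all of
    them, so every group keeps harvestable members for record generation).
    """
    config.validate()
    if config.species_pool_size < len(TROPHIC_GROUPS):
        raise ConfigurationError(
            "species_pool_size must cover all four trophic groups"
        )
    rng = _rng(config, 1)
    n = config.species_pool_size
    groups = [TROPHIC_GROUPS[i % len(TROPHIC_GROUPS)] for i in range(n)]
    lw_a = 10.0 ** rng.uniform(-2.2, -1.4, n)
    lw_b = rng.uniform(2.8, 3.2, n)
    length = rng.uniform(8.0, 35.0, n)
    df = pd.DataFrame(
        {
            "taxon_id": [f"SP{i:03d}" for i in range(n)],
            "lw_a": lw_a,
            "lw_b": lw_b,
            "trophic_group": groups,
            "typical_length_cm": length,
            "shark_or_jack": False,
        }
    )
    pisc = df.index[df["trophic_group"] == "piscivore"]
    n_flag = min(len(pisc) - 1, max(0, int(round(0.15 * len(pisc)))))
    if n_flag > 0:
        df.loc[rng.choice(pisc, size=n_flag, replace=False), "shark_or_jack"] = True
    return df


def _effect_bounds(config: SimulationConfig, name: str) -> tuple[float, float]:
    if name in config.covariate_ranges:
        return config.covariate_ranges[name]
    return (0.0, 1.0)  # decay effects ignore bounds


def simulate_islands(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Island covariates plus ground truth expected biomass.

    Returns
    -------
    (islands, truth)
        ``islands`` mirrors the real covariate-table schema (region, island,
        atoll, forereef_ha, pop, distant_pop, chl, wv, sstl) plus latent
        benthic means ``hc_mean``/``cx_mean``. ``truth`` has per-group
        expected biomass at the island's covariates, the same with human
        terms zeroed, and the implied depletion fraction.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.n_islands
    r = config.covariate_ranges

    atoll = (rng.random(n) < config.p_atoll).astype(int)
    area = np.clip(rng.lognormal(math.log(2000.0), 1.0, n), 100.0, 31000.0)
    inhabited = rng.random(n) < config.p_inhabited
    if inhabited.all():
        inhabited[0] = False  # keep HUM = 0 inside the observed range
    density = np.where(
        inhabited, np.clip(rng.lognormal(0.0, 1.5, n), 0.005, 40.0), 0.0
    )
    pop = np.round(density * area).astype(int)
    has_distant = rng.random(n) < config.p_distant
    ddens = np.where(
        has_distant, np.clip(rng.lognormal(1.0, 1.5, n), 0.005, 100.0), 0.0
    )
    distant = np.round(ddens * area).astype(int)

    cols = {
        "CHL": rng.uniform(*r["CHL"], n),
        "WV": rng.uniform(*r["WV"], n),
        "SSTL": rng.uniform(*r["SSTL"], n),
        "HC": rng.uniform(*r["HC"], n),
        "CX": rng.uniform(*r["CX"], n),
    }
    hum = np.sqrt(pop / area)
    hdist = np.sqrt(distant / area)
    values = dict(cols, HUM=hum, HDIST=hdist, AT=atoll.astype(float))

    log_effect = np.zeros(n)
    log_effect_nohuman = np.zeros(n)
    for name, eff in config.true_effects.items():
        if name not in values:
            raise ConfigurationError(f"effect on unknown covariate {name!r}")
        lo, hi = _effect_bounds(config, name)
        contrib = eff(values[name], lo, hi)
        log_effect += contrib
        if name not in ("HUM", "HDIST"):
            log_effect_nohuman += contrib

    islands = pd.DataFrame(
        {
            "island_id": [f"ISL{i:03d}" for i in range(n)],
            "region": "SIM",
            "island": [f"ISL{i:03d}" for i in range(n)],
            "atoll": atoll,
            "forereef_ha": area,
            "pop": pop,
            "distant_pop": distant,
            "chl": cols["CHL"],
            "wv": cols["WV"],
            "sstl": cols["SSTL"],
            "hc_mean": cols["HC"],
            "cx_mean": cols["CX"],
        }
    )

    truth = pd.DataFrame({"island_id": islands["island_id"]})
    total = np.zeros(n)
    total_nh = np.zeros(n)
    for g in TROPHIC_GROUPS:
        base = config.base_biomass[g]
        truth[f"expected_{g}"] = base * np.exp(log_effect)
        truth[f"expected_nohuman_{g}"] = base * np.exp(log_effect_nohuman)
        total += truth[f"expected_{g}"]
        total_nh += truth[f"expected_nohuman_{g}"]
    truth["expected_total"] = total
    truth["expected_nohuman_total"] = total_nh
    truth["true_depletion"] = 1.0 - total / total_nh
    return islands, truth


def _allocate_sites(n_sites: int, fractions: list[float]) -> list[int]:
    """Largest-remainder allocation of sites to strata (each gets >= 0)."""
    raw = [n_sites * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rem = n_sites - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _records_for_mass(
    rng: np.random.Generator,
    pool: pd.DataFrame,
    target_mass_g: float,
    site_id: str,
    cylinder_id: int,
) -> list[dict]:
    """Fish records whose summed mass equals ``target_mass_g`` exactly.

    Picks one species, draws a typical length, fills with whole fish of
    that size, and absorbs the remainder in a single fish whose length is
    solved from the allometry.
    """
    if target_mass_g <= 0:
        return []
    sp = pool.iloc[int(rng.integers(len(pool)))]
    length = float(rng.lognormal(math.log(sp["typical_length_cm"]), 0.25))
    unit = sp["lw_a"] * length ** sp["lw_b"]
    count = int(target_mass_g // unit)
    out = []
    if count > 0:
        out.append(
            {
                "site_id": site_id,
                "cylinder_id": cylinder_id,
                "taxon_id": sp["taxon_id"],
                "count": count,
                "length_cm": length,
            }
        )
    rem = target_mass_g - count * unit
    if rem > 1e-9:
        out.append(
            {
                "site_id": site_id,
                "cylinder_id": cylinder_id,
                "taxon_id": sp["taxon_id"],
                "count": 1,
                "length_cm": float((rem / sp["lw_a"]) ** (1.0 / sp["lw_b"])),
            }
        )
    return out


def simulate_surveys(
    islands: pd.DataFrame,
    truth: pd.DataFrame,
    species: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired-cylinder fish records, site table, and stratum areas.

    Site totals per trophic group are gamma draws with shape
    ``config.dispersion`` around the island's expected biomass; both
    cylinders of a site carry the same density so their mean equals the site
    draw, and each cylinder's records sum exactly to its target mass.

    Raises
    ------
    ConfigurationError
        If an island is missing from the truth table.
    """
    config.validate()
    missing = set(islands["island_id"]) - set(truth["island_id"])
    if missing:
        raise ConfigurationError(f"truth missing islands: {sorted(missing)}")
    rng = _rng(config, 3)
    area_m2 = cylinder_area_m2()
    shape = config.dispersion

    pools = {
        g: species[(species["trophic_group"] == g) & ~species["shark_or_jack"]]
        for g in TROPHIC_GROUPS
    }
    for g, pool in pools.items():
        if pool.empty:
            raise ConfigurationError(f"no harvestable species in group {g!r}")
    shark_pool = species[species["shark_or_jack"]]

    truth_ix = truth.set_index("island_id")
    labels = [s[0] for s in config.strata_spec]
    area_fracs = [s[1] for s in config.strata_spec]
    alloc_fracs = [s[2] for s in config.strata_spec]

    site_rows, record_rows, strata_rows = [], [], []
    for _, isl in islands.iterrows():
        iid = isl["island_id"]
        for lab, frac in zip(labels, area_fracs):
            strata_rows.append(
                {"island_id": iid, "stratum": lab, "area_ha": frac * isl["forereef_ha"]}
            )
        if isinstance(config.sites_per_island, tuple):
            lo, hi = config.sites_per_island
            n_sites = int(rng.integers(lo, hi + 1))
        else:
            n_sites = int(config.sites_per_island)
        counts = _allocate_sites(n_sites, alloc_fracs)
        mu = {g: truth_ix.loc[iid, f"expected_{g}"] for g in TROPHIC_GROUPS}
        k = 0
        for lab, n_h in zip(labels, counts):
            for _ in range(n_h):
                sid = f"{iid}-S{k:03d}"
                k += 1
                hc = float(np.clip(isl["hc_mean"] + rng.normal(0, 5.0), 0.5, 95.0))
                cx = float(np.clip(isl["cx_mean"] + rng.normal(0, 0.08), 0.05, 2.5))
                mpa = bool(isl["pop"] > 0 and rng.random() < config.mpa_fraction)
                site_rows.append(
                    {
                        "site_id": sid,
                        "island_id": iid,
                        "stratum": lab,
                        "depth_bin": lab,
                        "mpa_strict": mpa,
                        "hard_coral_pct": hc,
                        "complexity_m": cx,
                        "n_cylinders": 2,
                    }
                )
                for g in TROPHIC_GROUPS:
                    dens = float(rng.gamma(shape, mu[g] / shape))
                    for cyl in (1, 2):
                        record_rows.extend(
                            _records_for_mass(
                                rng, pools[g], dens * area_m2, sid, cyl
                            )
                        )
                if config.shark_biomass_gm2 > 0 and not shark_pool.empty:
                    dens = float(
                        rng.gamma(shape, config.shark_biomass_gm2 / shape)
                    )
                    for cyl in (1, 2):
                        record_rows.extend(
                            _records_for_mass(
                                rng, shark_pool, dens * area_m2, sid, cyl
                            )
                        )

    records = pd.DataFrame(
        record_rows,
        columns=["site_id", "cylinder_id", "taxon_id", "count", "length_cm"],
    )
    sites = pd.DataFrame(site_rows)
    strata = pd.DataFrame(strata_rows)
    return records, sites, strata


def simulate_calibration_pairs(
    n: int = 15,
    slope: float = 0.2,
    intercept: float = 0.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired (categorical 1-5 score, measured height m) calibration table.

    Heights are ``intercept + slope * category`` plus Gaussian noise,
    clipped at zero.
    """
    if n < 3:
        raise ConfigurationError("need at least 3 calibration pairs")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    cats = (np.arange(n) % 5 + 1).astype(float)
    heights = intercept + slope * cats + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"category": cats, "height_m": np.clip(heights, 0.0, None)})


def simulate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Run the full generator; returns all tables keyed by name."""
    species = simulate_species_table(config)
    islands, truth = simulate_islands(config)
    records, sites, strata = simulate_surveys(islands, truth, species, config)
    return {
        "species": species,
        "islands": islands,
        "truth": truth,
        "fish_records": records,
        "sites": sites,
        "strata": strata,
    }


def write_dataset(tables: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Write every generated table as ``<name>.csv`` under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(str(path))
    return written


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
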