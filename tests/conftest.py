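import numpy as np
import pandas as pd
import pytest

from reefbaselines import aggregate as agg
from reefbaselines import survey as sv
from reefbaselines import synthetic as syn
from reefbaselines.datasets import load_island_covariates


@pytest.fixture(scope="session")
def island_covariates():
    return load_island_covariates()


@pytest.fixture(scope="session")
def covariate_table(island_covariates):
    """Fixture table with HUM/HDIST/AT derived."""
    return agg.build_covariates(island_covariates)


@pytest.fixture(scope="session")
def toy_species():
    return pd.DataFrame(
        {
            "taxon_id": ["A", "B", "C", "D", "SHARK"],
            "lw_a": [0.01, 0.02, 0.015, 0.012, 0.008],
            "lw_b": [3.0, 2.9, 3.1, 3.0, 3.1],
            "trophic_group": [
                "primary",
                "secondary",
                "planktivore",
                "piscivore",
                "piscivore",
            ],
            "shark_or_jack": [False, False, False, False, True],
        }
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic dataset shared by read-only tests."""
    cfg = syn.SimulationConfig(n_islands=12, sites_per_island=10, seed=42)
    return syn.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_island_table(small_dataset):
    d = small_dataset
    bio = sv.site_biomass(d["fish_records"], d["species"], d["sites"])
    site = bio.merge(
        d["sites"][
            ["site_id", "island_id", "stratum", "hard_coral_pct", "complexity_m"]
        ],
        on="site_id",
    )
    summary = agg.aggregate_islands(site, d["strata"])
    covs = agg.build_covariates(d["islands"])
    return agg.build_island_table(summary, covs)


def rng(seed=0):
    return np.random.default_rng(seed)
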