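"""End-to-end orchestration: simulate -> site biomass -> island aggregation
-> collinearity screen -> model ensembles -> counterfactual baselines ->
report, from a single config, with deterministic seeding and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aggregate as agg
from . import baseline as bl
from . import ensemble as ens
from . import screen as scr
from . import survey as sv
from . import synthetic as syn

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)

RESPONSES = {
    "all": "mean_total",
    "primary": "mean_primary",
    "secondary": "mean_secondary",
    "planktivore": "mean_planktivore",
    "piscivore": "mean_piscivore",
}


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    simulation: syn.SimulationConfig | None = None
    input_dir: str | None = None  # read pre-existing CSVs instead of simulating
    min_sites: int = 12
    max_cv: float = 0.40
    r_threshold: float = 0.8
    weight_cutoff: float = 0.05
    responses: list[str] = field(default_factory=lambda: ["all"])
    predictors: list[str] | None = None
    basis_dim: int = 5
    pooling: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.weight_cutoff < 1:
            raise ValueError("weight_cutoff must be in (0, 1)")
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown responses: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Schema/invariant checks with row-level diagnostics.

    Returns a list of violation messages (empty when clean).
    """
    errors: list[str] = []
    req = {
        "fish_records": {"site_id", "cylinder_id", "taxon_id", "count", "length_cm"},
        "species": {"taxon_id", "lw_a", "lw_b", "trophic_group", "shark_or_jack"},
        "sites": {"site_id", "island_id", "stratum"},
        "strata": {"island_id", "stratum", "area_ha"},
        "islands": {"island_id", "forereef_ha", "pop", "distant_pop"},
    }
    for name, cols in req.items():
        if name not in tables:
            errors.append(f"{name}: table missing")
            continue
        missing = cols - set(tables[name].columns)
        if missing:
            errors.append(f"{name}: missing columns {sorted(missing)}")
    if errors:
        return errors

    rec, spp = tables["fish_records"], tables["species"]
    if (rec["count"] < 0).any():
        bad = rec.index[rec["count"] < 0].tolist()[:5]
        errors.append(f"fish_records: negative counts at rows {bad}")
    if (rec["length_cm"] <= 0).any():
        bad = rec.index[rec["length_cm"] <= 0].tolist()[:5]
        errors.append(f"fish_records: nonpositive lengths at rows {bad}")
    unresolved = sorted(set(rec["taxon_id"]) - set(spp["taxon_id"]))
    if unresolved:
        errors.append(f"fish_records: unresolved taxa {unresolved[:10]}")
    if spp["taxon_id"].duplicated().any():
        errors.append("species: duplicated taxon_id rows")
    if (spp["lw_a"] <= 0).any() or (spp["lw_b"] <= 0).any():
        errors.append("species: nonpositive length-weight parameters")
    groups = set(spp["trophic_group"])
    missing_groups = set(sv.TROPHIC_GROUPS) - groups
    if missing_groups:
        errors.append(f"species: trophic groups unrepresented: {sorted(missing_groups)}")

    isl = tables["islands"]
    neg = isl.index[isl["forereef_ha"] <= 0].tolist()
    if neg:
        errors.append(f"islands: nonpositive forereef area at rows {neg}")
    strata = tables["strata"]
    if (strata["area_ha"] <= 0).any():
        bad = strata.index[strata["area_ha"] <= 0].tolist()
        errors.append(f"strata: nonpositive areas at rows {bad}")
    orphan = sorted(set(tables["sites"]["island_id"]) - set(isl["island_id"]))
    if orphan:
        errors.append(f"sites: islands without metadata: {orphan[:10]}")
    return errors


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; writes CSV/JSON outputs and returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}
    import reefbaselines

    manifest["versions"] = {
        "reefbaselines": reefbaselines.__version__,
        "pandas": pd.__version__,
    }

    # stage 1: simulate or load
    if config.simulate:
        sim = config.simulation or syn.SimulationConfig()
        sim = syn.with_seed(sim, config.seed)
        tables = syn.simulate_dataset(sim)
        syn.write_dataset(tables, out / "inputs")
        for f in sorted((out / "inputs").glob("*.csv")):
            manifest["inputs"][f.name] = _sha256(f)
    else:
        if config.input_dir is None:
            raise ValueError("input_dir required when simulate=False")
        src = Path(config.input_dir)
        tables = {
            name: pd.read_csv(src / f"{name}.csv")
            for name in ("fish_records", "species", "sites", "strata", "islands")
        }
        for name in tables:
            manifest["inputs"][f"{name}.csv"] = _sha256(src / f"{name}.csv")
    manifest["stages"]["simulate"] = {
        "n_records": len(tables["fish_records"]),
        "n_sites": len(tables["sites"]),
        "n_islands": len(tables["islands"]),
    }

    violations = validate_inputs(tables)
    if violations:
        raise RuntimeError(f"stage validate: input violations: {violations}")

    # stage 2: site biomass
    records, sites, excl_log = sv.apply_exclusions(
        tables["fish_records"], tables["species"], tables["sites"]
    )
    site_bio = sv.site_biomass(records, tables["species"], sites)
    site_table = site_bio.merge(
        sites[
            [
                c
                for c in (
                    "site_id",
                    "island_id",
                    "stratum",
                    "hard_coral_pct",
                    "complexity_m",
                )
                if c in sites.columns
            ]
        ],
        on="site_id",
    )
    site_table.to_csv(out / "site_biomass.csv", index=False)
    manifest["stages"]["biomass"] = {"n_sites": len(site_table), **excl_log}

    # stage 3: island aggregation
    islands_meta = tables["islands"]
    strata = tables["strata"]
    if config.pooling:
        islands_meta, site_table, strata = agg.pool_reef_areas(
            islands_meta, config.pooling, site_table, strata
        )
    summary = agg.aggregate_islands(site_table, strata)
    retained, excluded = agg.filter_islands(summary, config.min_sites, config.max_cv)
    covs = agg.build_covariates(islands_meta)
    island_table = agg.build_island_table(retained, covs)
    island_table.to_csv(out / "island_table.csv", index=False)
    manifest["stages"]["aggregate"] = {
        "n_islands": len(retained),
        "n_excluded": len(excluded),
    }

    # stage 4: collinearity screen
    if config.predictors is None:
        candidates = [
            p for p in ens.PREDICTORS if p in island_table.columns
        ]
        predictors = [
            p for p in candidates if island_table[p].nunique() > 1
        ]
    else:
        predictors = list(config.predictors)
    report = scr.screen_predictors(island_table, predictors, config.r_threshold)
    (out / "screen_report.json").write_text(json.dumps(report, indent=2))
    constraints = [tuple(p) for p in report["exclusion_pairs"]]
    manifest["stages"]["screen"] = {
        "n_predictors": len(predictors),
        "n_constraints": len(constraints),
    }

    # stage 5: ensembles per response
    ensembles: dict[str, ens.EnsembleResult] = {}
    for resp in config.responses:
        col = RESPONSES[resp]
        result = ens.fit_ensemble(
            island_table,
            col,
            predictors,
            constraints,
            weight_cutoff=config.weight_cutoff,
            basis_dim=config.basis_dim,
        )
        ensembles[resp] = result
        tab = result.table()
        tab.to_csv(out / f"ensemble_{resp}.csv", index=False)
    manifest["stages"]["fit"] = {
        resp: {
            "n_models": len(e.fits),
            "n_retained": len(e.retained),
            "n_failed": len(e.failed),
        }
        for resp, e in ensembles.items()
    }

    # stage 6: counterfactual baselines (total-biomass response)
    key = "all" if "all" in ensembles else config.responses[0]
    baselines = bl.build_baseline_table(
        ensembles[key], island_table, RESPONSES[key], RESPONSES[key].replace("mean_", "se_")
    )
    baselines.to_csv(out / "baselines.csv", index=False)
    manifest["stages"]["predict"] = {"n_islands": len(baselines)}

    # stage 7: reference report
    report_out = bl.reference_report(baselines, island_table)
    (out / "report.json").write_text(json.dumps(report_out, indent=2, default=str))
    manifest["stages"]["report"] = {
        "n_remote": len(report_out["remote"]),
        "n_populated": len(report_out["populated"]),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
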