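"""Counterfactual no-human baselines and depletion reference points.

Predicts island biomass with the human-density covariates set to zero
(everything else unchanged), compares with the observed survey estimate, and
expresses the deficit as a depletion fraction with delta-method confidence
intervals. Islands are classed as human-populated or remote-uninhabited
(zero residents, plus configured no-harvest islands with caretaker
populations).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .ensemble import HUMAN_PREDICTORS, EnsembleResult, model_average_predict

__all__ = [
    "predict_no_humans",
    "depletion",
    "build_baseline_table",
    "reference_report",
    "DEFAULT_NO_HARVEST",
]

#: Reef areas with small resident caretaker/researcher populations but a
#: prohibition on reef-fish harvest; treated as remote-uninhabited.
DEFAULT_NO_HARVEST = ("Midway", "Palmyra")

Z95 = 1.959963984540054


def predict_no_humans(
    ensemble: EnsembleResult,
    table: pd.DataFrame,
    human_terms: Sequence[str] = HUMAN_PREDICTORS,
) -> pd.DataFrame:
    """Model-averaged prediction with human covariates zeroed.

    Uses the retained (weight > cutoff) models with renormalized weights.

    Returns
    -------
    DataFrame ``island_id, pred_mean, pred_se``.

    Raises
    ------
    ValueError
        If the retained set is empty or a predictor column is missing.
    """
    retained = ensemble.retained
    if not retained:
        raise ValueError("ensemble has no retained models")
    needed = {p for f in retained for p in f.spec}
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"island table missing covariates: {sorted(missing)}")
    counterfactual = table.copy()
    for term in human_terms:
        if term in counterfactual.columns:
            counterfactual[term] = 0.0
    mean, se = model_average_predict(retained, counterfactual)
    return pd.DataFrame(
        {
            "island_id": table["island_id"].to_numpy(),
            "pred_mean": mean,
            "pred_se": se,
        }
    )


def depletion(observed, predicted, observed_se=0.0, predicted_se=0.0):
    """Depletion fraction ``1 - observed/predicted`` with a delta-method SE.

    Treats observed and predicted errors as independent:
    ``var = (obs/pred)^2 * ((se_obs/obs)^2 + (se_pred/pred)^2)``.

    Returns
    -------
    (depletion, se) as floats or arrays.

    Raises
    ------
    ValueError
        On nonpositive predicted biomass.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    so = np.asarray(observed_se, dtype=float)
    sp = np.asarray(predicted_se, dtype=float)
    if np.any(pred <= 0):
        raise ValueError("predicted biomass must be positive")
    ratio = obs / pred
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(obs > 0, (so / obs) ** 2, 0.0) + (sp / pred) ** 2
    se = np.abs(ratio) * np.sqrt(rel)
    dep = 1.0 - ratio
    if dep.ndim == 0:
        return float(dep), float(se)
    return dep, se


def build_baseline_table(
    ensemble: EnsembleResult,
    table: pd.DataFrame,
    response_mean: str = "mean_total",
    response_se: str = "se_total",
    no_harvest: Sequence[str] = DEFAULT_NO_HARVEST,
) -> pd.DataFrame:
    """Per-island observed vs counterfactual biomass and depletion.

    Depletion is reported only for human-populated islands;
    remote-uninhabited islands (zero residents or configured no-harvest
    areas) get the baseline comparison with depletion left NaN.
    """
    pred = predict_no_humans(ensemble, table)
    out = table[["island_id", response_mean, response_se]].rename(
        columns={response_mean: "obs_mean", response_se: "obs_se"}
    )
    out = out.merge(pred, on="island_id")

    populated = (table["HUM"].to_numpy() > 0) & ~table["island_id"].isin(
        no_harvest
    ).to_numpy()
    out["status"] = np.where(populated, "populated", "remote-uninhabited")

    dep, dep_se = depletion(
        out["obs_mean"], out["pred_mean"], out["obs_se"], out["pred_se"]
    )
    out["depletion"] = np.where(populated, dep, np.nan)
    out["depletion_se"] = np.where(populated, dep_se, np.nan)
    for stem in ("obs", "pred"):
        out[f"{stem}_lo"] = out[f"{stem}_mean"] - Z95 * out[f"{stem}_se"]
        out[f"{stem}_hi"] = out[f"{stem}_mean"] + Z95 * out[f"{stem}_se"]
    return out


def reference_report(
    estimates: pd.DataFrame,
    table: pd.DataFrame | None = None,
) -> dict:
    """Two-panel reference-point layout.

    Remote-uninhabited areas sorted from high to low CHL; human-populated
    areas from low to high local human density (HUM). ``table`` supplies the
    CHL/HUM sort keys when they are not already columns of ``estimates``.

    Returns a dict with ``remote`` and ``populated`` row-record lists plus
    summary statistics.
    """
    if estimates.empty:
        raise ValueError("no baseline estimates to report")
    df = estimates.copy()
    if table is not None:
        keys = [c for c in ("CHL", "HUM") if c not in df.columns]
        if keys:
            df = df.merge(table[["island_id", *keys]], on="island_id", how="left")

    remote = df[df["status"] == "remote-uninhabited"]
    populated = df[df["status"] == "populated"]
    if "CHL" in remote.columns:
        remote = remote.sort_values("CHL", ascending=False)
    if "HUM" in populated.columns:
        populated = populated.sort_values("HUM", ascending=True)

    dep = populated["depletion"].dropna()
    return {
        "remote": remote.to_dict(orient="records"),
        "populated": populated.to_dict(orient="records"),
        "n_islands": int(len(df)),
        "depletion_range": (
            [float(dep.min()), float(dep.max())] if len(dep) else None
        ),
    }
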