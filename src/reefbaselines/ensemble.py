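"""Constrained all-subsets gamma-GAM ensemble with AICc model averaging.

Enumerates every admissible predictor subset (the null model included,
constrained pairs never co-occurring), fits each candidate as a gamma
log-link additive model (basis dimension 5 per continuous smooth, the atoll
flag as a parametric 0/1 term), ranks by small-sample-corrected AIC, and
derives Akaike weights, per-predictor importance, model-averaged predictions
with unconditional standard errors, and scaled smoother profiles.

Weights and variable importance are always computed over the full enumerated
model space; prediction averages over the retained (weight > cutoff) subset
with renormalized weights.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam import FitFailure, GammaGAM, GammaGAMFit

__all__ = [
    "PREDICTORS",
    "FACTOR_PREDICTORS",
    "ModelFit",
    "EnsembleResult",
    "enumerate_models",
    "aicc",
    "akaike_weights",
    "variable_importance",
    "fit_model",
    "fit_ensemble",
    "model_average_predict",
    "smoother_profile",
]

logger = logging.getLogger(__name__)

#: Full predictor set, alphabetical.
PREDICTORS = ("AT", "CHL", "CX", "HC", "HDIST", "HUM", "SSTL", "WV")
#: Predictors entered as parametric 0/1 terms rather than smooths.
FACTOR_PREDICTORS = frozenset({"AT"})
#: Covariates zeroed for counterfactual no-human prediction.
HUMAN_PREDICTORS = ("HUM", "HDIST")

DEFAULT_WEIGHT_CUTOFF = 0.05
DEFAULT_CONSTRAINTS = (("SSTL", "WV"),)


def enumerate_models(
    predictors: Sequence[str],
    constraints: Iterable[tuple[str, str]] = (),
) -> list[tuple[str, ...]]:
    """All predictor subsets violating no mutual-exclusion constraint.

    Includes the empty (intercept-only) model. Deterministic order: by
    subset size, then lexicographically.
    """
    preds = list(predictors)
    cons = [tuple(sorted(c)) for c in constraints]
    for a, b in cons:
        if a not in preds or b not in preds:
            raise ValueError(f"constraint ({a}, {b}) references unknown predictor")
    specs: list[tuple[str, ...]] = []
    for mask in range(1 << len(preds)):
        subset = tuple(p for i, p in enumerate(preds) if mask >> i & 1)
        if any(a in subset and b in subset for a, b in cons):
            continue
        specs.append(tuple(sorted(subset)))
    specs.sort(key=lambda s: (len(s), s))
    return specs


def aicc(log_likelihood: float, k: float, n: int) -> float:
    """AICc = -2*ll + 2k + 2k(k+1)/(n-k-1); ``k`` may be fractional.

    Raises
    ------
    ValueError
        If ``n - k - 1 <= 0``.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for k={k}, n={n}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aicc_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Delta-AICc and Akaike weights over a model set.

    Non-finite entries get zero weight. Raises if no entry is finite.
    """
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    best = a[finite].min()
    delta = a - best
    rel = np.where(finite, np.exp(-0.5 * np.where(finite, delta, 0.0)), 0.0)
    return delta, rel / rel.sum()


def variable_importance(
    specs: Sequence[tuple[str, ...]],
    weights: Sequence[float],
    predictors: Sequence[str] | None = None,
) -> pd.Series:
    """Per-predictor importance: total Akaike weight of models containing it."""
    if predictors is None:
        predictors = sorted({p for s in specs for p in s})
    w = np.asarray(weights, dtype=float)
    return pd.Series(
        {p: float(w[[p in s for s in specs]].sum()) for p in predictors},
        name="importance",
    )


@dataclass
class ModelFit:
    """One candidate model within an ensemble."""

    spec: tuple[str, ...]
    fit: GammaGAMFit
    k: float  #: effective df incl. intercept and one for the gamma scale
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan

    @property
    def adj_r2(self) -> float:
        return self.fit.adj_r2

    def predict(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return self.fit.predict(data)


@dataclass
class EnsembleResult:
    """All fitted candidates for one response, ranked by AICc."""

    response: str
    fits: list[ModelFit]
    importance: pd.Series
    weight_cutoff: float
    failed: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def retained(self) -> list[ModelFit]:
        return [f for f in self.fits if f.weight > self.weight_cutoff]

    def table(self) -> pd.DataFrame:
        """Ranked summary (term flags, d.f., adj-R2, AICc, delta, weight)."""
        preds = list(self.importance.index)
        rows = []
        for f in self.fits:
            row = {p: ("X" if p in f.spec else "") for p in preds}
            row.update(
                df=f.k,
                adj_r2=f.adj_r2,
                aicc=f.aicc,
                delta_aicc=f.delta_aicc,
                weight=f.weight,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _split_terms(spec: Sequence[str]) -> tuple[tuple[str, ...], tuple[str, ...]]:
    linear = tuple(p for p in spec if p in FACTOR_PREDICTORS)
    smooth = tuple(p for p in spec if p not in FACTOR_PREDICTORS)
    return smooth, linear


def fit_model(
    table: pd.DataFrame,
    response: str,
    spec: Sequence[str],
    basis_dim: int = 5,
    alpha: float | None = None,
) -> ModelFit:
    """Fit one candidate model and compute its AICc.

    ``k`` is the total effective degrees of freedom of the penalized fit
    (hat-matrix trace, intercept included) plus one for the gamma scale
    parameter.

    Raises
    ------
    FitFailure
        On non-convergence or when AICc is undefined (k too close to n).
    """
    smooth, linear = _split_terms(spec)
    engine = GammaGAM(basis_dim=basis_dim, alpha=alpha)
    fit = engine.fit(table, response, smooth_terms=smooth, linear_terms=linear)
    k = fit.edf + 1.0
    n = fit.nobs
    if n - k - 1 <= 0:
        raise FitFailure(f"model {spec} consumes too many df (k={k:.1f}, n={n})")
    return ModelFit(spec=tuple(spec), fit=fit, k=k, aicc=aicc(fit.llf, k, n))


def fit_ensemble(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str] = PREDICTORS,
    constraints: Iterable[tuple[str, str]] = DEFAULT_CONSTRAINTS,
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF,
    basis_dim: int = 5,
) -> EnsembleResult:
    """Enumerate, fit, and rank all admissible models for one response.

    Candidates that fail to converge are dropped with a warning; weights are
    normalized over the converged set.
    """
    specs = enumerate_models(predictors, constraints)
    fits: list[ModelFit] = []
    failed: list[tuple[str, ...]] = []
    for spec in specs:
        try:
            fits.append(fit_model(table, response, spec, basis_dim=basis_dim))
        except (FitFailure, ValueError) as err:
            failed.append(tuple(spec))
            logger.warning("model %s dropped: %s", spec, err)
    if not fits:
        raise FitFailure(f"no model converged for response {response!r}")
    if failed:
        warnings.warn(
            f"{len(failed)} of {len(specs)} candidate models failed and were "
            "dropped",
            stacklevel=2,
        )
    delta, w = akaike_weights([f.aicc for f in fits])
    for f, d, wi in zip(fits, delta, w):
        f.delta_aicc = float(d)
        f.weight = float(wi)
    fits.sort(key=lambda f: f.aicc)
    imp = variable_importance(
        [f.spec for f in fits], [f.weight for f in fits], list(predictors)
    )
    return EnsembleResult(
        response=response,
        fits=fits,
        importance=imp,
        weight_cutoff=weight_cutoff,
        failed=failed,
    )


def model_average_predict(
    fits: Sequence[ModelFit],
    data: pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted model-averaged prediction with unconditional SE.

    Weights default to the fits' Akaike weights, renormalized over the given
    set. Averaging happens on the response scale; the unconditional variance
    follows the standard model-averaging rule
    ``se^2 = sum_i w_i * (se_i^2 + (yhat_i - yavg)^2)``.

    Raises
    ------
    ValueError
        On an empty fit set.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("model_average_predict needs a non-empty fit set")
    if weights is None:
        weights = [f.weight for f in fits]
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("non-positive total weight")
    w = w / w.sum()

    preds = np.array([f.predict(data)[0] for f in fits])
    ses = np.array([f.predict(data)[1] for f in fits])
    avg = w @ preds
    var = w @ (ses**2 + (preds - avg) ** 2)
    return avg, np.sqrt(var)


def smoother_profile(
    fits: ModelFit | Sequence[ModelFit],
    table: pd.DataFrame,
    predictor: str,
    n_grid: int = 100,
    reference: str | None = None,
) -> pd.DataFrame:
    """Partial-effect profile of one predictor, scaled to a reference point.

    The predictor sweeps ``n_grid`` equally spaced values over its observed
    range while every other predictor is held at its mean (the atoll flag at
    its mean as a fraction). The response is additionally reported as a
    proportion of its value at the reference point: predictor = 0 for the
    human-density terms, = observed minimum otherwise (overridable via
    ``reference`` = ``"zero"`` | ``"min"``).

    Accepts a single model or a set of models averaged with their weights;
    models not containing the predictor are allowed in the set (their
    prediction is simply flat in it), but at least one must contain it.

    Returns
    -------
    DataFrame with columns ``predictor, value, mean, se, lo, hi, scaled``
    (lo/hi are 95% bounds on the unscaled mean).
    """
    fitlist = [fits] if isinstance(fits, ModelFit) else list(fits)
    if not any(predictor in f.spec for f in fitlist):
        raise ValueError(f"predictor {predictor!r} absent from all supplied models")

    terms = sorted({p for f in fitlist for p in f.spec})
    lo, hi = float(table[predictor].min()), float(table[predictor].max())
    grid = np.linspace(lo, hi, n_grid)
    newdata = pd.DataFrame(
        {t: np.full(n_grid, float(table[t].mean())) for t in terms}
    )
    newdata[predictor] = grid

    if len(fitlist) == 1:
        mean, se = fitlist[0].predict(newdata)
    else:
        mean, se = model_average_predict(fitlist, newdata)

    if reference is None:
        reference = "zero" if predictor in HUMAN_PREDICTORS else "min"
    if reference == "zero":
        ref_x = 0.0
        if not lo <= 0.0 <= hi:
            ref_x = lo  # zero outside observed range; fall back to the min
    elif reference == "min":
        ref_x = lo
    else:
        raise ValueError(f"unknown reference {reference!r}")
    refdata = newdata.iloc[[0]].copy()
    refdata[predictor] = ref_x
    ref_mean = (
        fitlist[0].predict(refdata)[0]
        if len(fitlist) == 1
        else model_average_predict(fitlist, refdata)[0]
    )[0]

    return pd.DataFrame(
        {
            "predictor": predictor,
            "value": grid,
            "mean": mean,
            "se": se,
            "lo": mean - 1.96 * se,
            "hi": mean + 1.96 * se,
            "scaled": mean / ref_mean,
        }
    )
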