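"""Predictor collinearity screening.

Pearson correlations over the island table (the atoll flag coded 0/1, i.e.
point-biserial against continuous predictors), variance inflation factors
within candidate predictor subsets, and the mutual-exclusion constraints fed
to model enumeration.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["pearson_matrix", "vif", "exclusion_pairs", "screen_predictors"]

DEFAULT_R_THRESHOLD = 0.8


def pearson_matrix(table: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix over ``predictors``.

    Raises
    ------
    ValueError
        With fewer than 3 rows, missing values, or a constant column
        (named in the message).
    """
    sub = table[list(predictors)].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 islands for correlations")
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in predictors: {bad}")
    const = [c for c in sub.columns if sub[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant predictor column(s): {const}")
    return sub.corr(method="pearson")


def vif(table: pd.DataFrame, subset: Sequence[str]) -> pd.Series:
    """Variance inflation factors within a predictor subset.

    VIF_j = 1 / (1 - R^2_j) from the OLS regression (with intercept) of
    predictor j on the remaining subset members. Perfect collinearity is
    reported as ``inf``.

    Raises
    ------
    ValueError
        If the subset has fewer than 2 predictors or not more rows than
        predictors.
    """
    cols = list(subset)
    if len(cols) < 2:
        raise ValueError("VIF needs a subset of at least 2 predictors")
    X = table[cols].astype(float).to_numpy()
    n = X.shape[0]
    if n <= len(cols):
        raise ValueError("need more islands than predictors for VIF")
    out = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"constant predictor column: {name}")
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def exclusion_pairs(
    corr: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    declared: Iterable[tuple[str, str]] = (),
) -> set[tuple[str, str]]:
    """Predictor pairs barred from co-occurring in one model.

    The union of explicitly declared pairs and all pairs with
    ``|r| >= r_threshold``. Pairs are returned as sorted 2-tuples.
    """
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must be in (0, 1]")
    pairs = {tuple(sorted(p)) for p in declared}
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if abs(corr.loc[a, b]) >= r_threshold:
                pairs.add(tuple(sorted((a, b))))
    return pairs


def screen_predictors(
    table: pd.DataFrame,
    predictors: Sequence[str],
    r_threshold: float = DEFAULT_R_THRESHOLD,
    declared: Iterable[tuple[str, str]] = (),
) -> dict:
    """Full screening report: correlation matrix, per-subset VIFs, and
    exclusion constraints.

    VIFs are computed for each admissible subset obtained by dropping one
    member of every exclusion pair from the full predictor list (for the
    single WV/SSTL constraint: once without SSTL, once without WV).

    Returns a JSON-serialisable dict.
    """
    preds = list(predictors)
    corr = pearson_matrix(table, preds)
    pairs = exclusion_pairs(corr, r_threshold, declared)

    subsets: list[list[str]] = [preds]
    for a, b in sorted(pairs):
        subsets = [
            [p for p in s if p != drop] for s in subsets for drop in (a, b)
        ]
    # dedupe, keep order
    seen, uniq = set(), []
    for s in subsets:
        key = tuple(s)
        if key not in seen:
            seen.add(key)
            uniq.append(s)

    vifs = {
        "+".join(s): vif(table, s).to_dict() for s in uniq if len(s) >= 2
    }
    max_vif = max((v for sub in vifs.values() for v in sub.values()), default=np.nan)
    return {
        "predictors": preds,
        "r_threshold": r_threshold,
        "pearson": corr.round(6).to_dict(),
        "exclusion_pairs": sorted(list(p) for p in pairs),
        "vif": vifs,
        "max_vif": float(max_vif),
    }
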