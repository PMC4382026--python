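"""Penalized gamma log-link additive regression backend.

Thin wrapper around :class:`statsmodels.gam.generalized_additive_model.GLMGam`
providing the pieces the ensemble machinery needs: a fixed basis dimension
per smooth, data-driven smoothness selection by generalized cross-validation,
effective degrees of freedom, and mean/SE prediction on the response scale
for new covariate rows.

Continuous terms get cubic B-spline bases of ``basis_dim`` functions
(including the constant absorbed by the model intercept, so ``basis_dim - 1``
free columns each) with a second-derivative roughness penalty; binary/factor
terms enter linearly. A single penalty weight shared across smooths is chosen
on a log-spaced grid by minimizing GCV = n * deviance / (n - edf)^2; models
without smooth terms reduce to an ordinary gamma GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = ["GammaGAM", "GammaGAMFit", "FitFailure"]

DEFAULT_BASIS_DIM = 5
DEFAULT_ALPHA_GRID = np.logspace(-3.0, 6.0, 13)


class FitFailure(RuntimeError):
    """Raised when a candidate model fails to converge or is degenerate."""


def _gamma_family():
    return sm.families.Gamma(link=sm.families.links.Log())


@dataclass
class GammaGAMFit:
    """A fitted gamma log-link additive model."""

    smooth_terms: tuple[str, ...]
    linear_terms: tuple[str, ...]
    llf: float
    edf: float  #: trace of the hat matrix (includes the intercept)
    scale: float
    deviance: float
    null_deviance: float
    alpha: float
    fitted: np.ndarray
    se_fit: np.ndarray  #: SE of the fitted mean, response scale
    nobs: int
    _result: object = field(repr=False)
    _smoother: object | None = field(repr=False)
    _ranges: dict[str, tuple[float, float]] = field(repr=False)

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.linear_terms) + tuple(self.smooth_terms)

    @property
    def adj_r2(self) -> float:
        """Deviance-based adjusted R^2: 1 - (dev/(n-edf)) / (null_dev/(n-1))."""
        n = self.nobs
        if self.null_deviance <= 0 or n - self.edf <= 0:
            return np.nan
        return 1.0 - (self.deviance / (n - self.edf)) / (
            self.null_deviance / (n - 1)
        )

    def _design(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        cols = [np.ones(n)]
        for t in self.linear_terms:
            cols.append(data[t].to_numpy(dtype=float))
        X = np.column_stack(cols)
        if self._smoother is not None:
            xs = np.column_stack(
                [
                    np.clip(data[t].to_numpy(dtype=float), *self._ranges[t])
                    for t in self.smooth_terms
                ]
            )
            X = np.column_stack([X, self._smoother.transform(xs)])
        return X

    def predict(self, data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Mean and SE of the predicted mean on the response scale.

        Smooth-term values outside the training range are clamped to it
        (the spline bases do not extrapolate).
        """
        X = self._design(data)
        params = np.asarray(self._result.params)
        cov = np.asarray(self._result.cov_params())
        eta = X @ params
        mu = np.exp(eta)
        quad = np.einsum("ij,jk,ik->i", X, cov, X)
        se_link = np.sqrt(np.maximum(quad, 0.0))  # clip numerical negatives
        return mu, mu * se_link  # delta method through the log link


class GammaGAM:
    """Factory for penalized gamma log-link additive fits.

    Parameters
    ----------
    basis_dim : spline basis dimension per smooth term (default 5, i.e. four
        free basis functions on top of the intercept).
    degree : B-spline degree (cubic by default).
    alpha_grid : candidate shared penalty weights for GCV selection.
    alpha : fixed penalty weight; bypasses GCV selection when given.
    """

    def __init__(
        self,
        basis_dim: int = DEFAULT_BASIS_DIM,
        degree: int = 3,
        alpha_grid: np.ndarray | None = None,
        alpha: float | None = None,
    ):
        if basis_dim <= degree:
            raise ValueError("basis_dim must exceed the spline degree")
        self.basis_dim = basis_dim
        self.degree = degree
        self.alpha_grid = (
            DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid)
        )
        self.alpha = alpha

    def fit(
        self,
        data: pd.DataFrame,
        response: str,
        smooth_terms: tuple[str, ...] = (),
        linear_terms: tuple[str, ...] = (),
    ) -> GammaGAMFit:
        """Fit ``response ~ intercept + linear_terms + s(smooth_terms)``.

        Raises
        ------
        FitFailure
            On non-convergence, non-finite likelihood, or a fit consuming
            nearly all degrees of freedom.
        ValueError
            If the response is not strictly positive.
        """
        y = data[response].to_numpy(dtype=float)
        if np.any(y <= 0) or np.any(~np.isfinite(y)):
            raise ValueError("gamma response must be strictly positive and finite")
        n = len(y)
        smooth_terms = tuple(smooth_terms)
        linear_terms = tuple(linear_terms)

        exog = np.column_stack(
            [np.ones(n)] + [data[t].to_numpy(dtype=float) for t in linear_terms]
        )

        if not smooth_terms:
            return self._fit_glm(y, exog, smooth_terms, linear_terms, n)

        xs = np.column_stack([data[t].to_numpy(dtype=float) for t in smooth_terms])
        ranges = {
            t: (float(xs[:, j].min()), float(xs[:, j].max()))
            for j, t in enumerate(smooth_terms)
        }
        smoother = BSplines(
            xs,
            df=[self.basis_dim] * len(smooth_terms),
            degree=[self.degree] * len(smooth_terms),
            include_intercept=False,
        )

        def _try(alpha: float):
            model = GLMGam(
                y,
                exog=exog,
                smoother=smoother,
                alpha=[alpha] * len(smooth_terms),
                family=_gamma_family(),
            )
            try:
                res = model.fit(maxiter=200)
            except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
                return None
            if not np.isfinite(res.llf) or not res.converged:
                return None
            return res

        if self.alpha is not None:
            best_alpha, best = self.alpha, _try(self.alpha)
        else:
            best, best_alpha, best_score = None, np.nan, np.inf
            for a in self.alpha_grid:
                res = _try(float(a))
                if res is None:
                    continue
                edf = float(res.hat_matrix_trace)
                if n - edf <= 1:
                    continue
                score = n * res.deviance / (n - edf) ** 2
                if score < best_score:
                    best, best_alpha, best_score = res, float(a), score
        if best is None:
            raise FitFailure(
                f"no converged fit for terms {linear_terms + smooth_terms}"
            )

        edf = float(best.hat_matrix_trace)
        X = np.column_stack([exog, smoother.basis])
        mu = np.asarray(best.fittedvalues)
        cov = np.asarray(best.cov_params())
        se_link = np.sqrt(
            np.maximum(np.einsum("ij,jk,ik->i", X, cov, X), 0.0)
        )
        return GammaGAMFit(
            smooth_terms=smooth_terms,
            linear_terms=linear_terms,
            llf=float(best.llf),
            edf=edf,
            scale=float(best.scale),
            deviance=float(best.deviance),
            null_deviance=float(best.null_deviance),
            alpha=best_alpha,
            fitted=mu,
            se_fit=mu * se_link,
            nobs=n,
            _result=best,
            _smoother=smoother,
            _ranges=ranges,
        )

    def _fit_glm(self, y, exog, smooth_terms, linear_terms, n) -> GammaGAMFit:
        model = sm.GLM(y, exog, family=_gamma_family())
        try:
            res = model.fit(maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as err:
            raise FitFailure(str(err)) from err
        if not np.isfinite(res.llf):
            raise FitFailure("non-finite likelihood")
        mu = np.asarray(res.fittedvalues)
        cov = np.asarray(res.cov_params())
        se_link = np.sqrt(
            np.maximum(np.einsum("ij,jk,ik->i", exog, cov, exog), 0.0)
        )
        return GammaGAMFit(
            smooth_terms=smooth_terms,
            linear_terms=linear_terms,
            llf=float(res.llf),
            edf=float(exog.shape[1]),
            scale=float(res.scale),
            deviance=float(res.deviance),
            null_deviance=float(res.null_deviance),
            alpha=0.0,
            fitted=mu,
            se_fit=mu * se_link,
            nobs=n,
            _result=res,
            _smoother=None,
            _ranges={},
        )
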