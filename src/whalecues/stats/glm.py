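"""GLM and linear-model wrappers returning a uniform results facade.

Count responses (new whale groups per trial) use a log-link Poisson GLM;
over-dispersed bird counts use negative-binomial regression with the
dispersion estimated by ML; respiratory rates use an ordinary linear model on
square-root-transformed values.  All fitters return a :class:`ModelFit`
facade with estimates, Wald standard errors, 95% CIs, log-likelihood and AIC,
so downstream model selection and contrasts treat them interchangeably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ModelFit", "fit_poisson_glm", "fit_negbin_glm", "fit_sqrt_lm"]


@dataclass
class ModelFit:
    """Uniform results container around a fitted statsmodels model."""

    model_name: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper (95%)
    pvalues: pd.Series
    llf: float
    aic: float
    converged: bool
    nobs: int
    extra: dict = field(default_factory=dict)  # theta, r2, flags ...
    sm_results: object | None = None

    def cov_params(self) -> np.ndarray:
        return np.asarray(self.sm_results.cov_params())

    def summary(self):
        return self.sm_results.summary()

    def __repr__(self) -> str:  # compact: name, k, AIC
        return (f"<ModelFit {self.model_name}: {len(self.params)} params, "
                f"AIC={self.aic:.2f}, converged={self.converged}>")


def _wrap(name: str, res, converged: bool, extra: dict | None = None) -> ModelFit:
    ci = res.conf_int()
    ci = pd.DataFrame(np.asarray(ci), index=res.params.index
                      if hasattr(res.params, "index") else None,
                      columns=["lower", "upper"])
    return ModelFit(
        model_name=name,
        params=pd.Series(res.params),
        bse=pd.Series(res.bse),
        conf_int=ci,
        pvalues=pd.Series(res.pvalues),
        llf=float(res.llf),
        aic=float(res.aic),
        converged=converged,
        nobs=int(res.nobs),
        extra=extra or {},
        sm_results=res,
    )


def _check_counts(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts != np.round(counts)):
        raise ValueError("counts must be integers")
    return counts


def _as_design(design) -> pd.DataFrame:
    X = pd.DataFrame(design)
    if not X.select_dtypes(exclude="number").empty:
        raise ValueError("design matrix must be numeric (encode factors first)")
    return X


def fit_poisson_glm(counts, design) -> ModelFit:
    """Log-link Poisson GLM with per-coefficient Wald z tests."""
    y = _check_counts(counts)
    X = _as_design(design)
    if np.all(y == 0):
        # the MLE sits on the boundary (log-mean -> -inf): no finite fit exists
        k = X.shape[1]
        idx = list(X.columns)
        nan = pd.Series(np.full(k, np.nan), index=idx)
        return ModelFit(
            model_name="poisson_glm",
            params=nan, bse=nan.copy(),
            conf_int=pd.DataFrame({"lower": nan, "upper": nan}),
            pvalues=nan.copy(), llf=0.0, aic=np.nan,
            converged=False, nobs=len(y),
            extra={"flag": "non-identifiable: all counts zero (boundary)"},
        )
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return _wrap("poisson_glm", res, converged=bool(res.converged))


def fit_negbin_glm(counts, design) -> ModelFit:
    """Negative-binomial (NB2) regression; dispersion estimated by ML.

    The reported ``extra['theta']`` is the size parameter (variance =
    mu + mu^2/theta); large theta means near-Poisson.
    """
    y = _check_counts(counts)
    X = _as_design(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.NegativeBinomial(y, X).fit(disp=False, maxiter=200)
    converged = bool(res.mle_retvals.get("converged", False))
    alpha = float(res.params.iloc[-1] if hasattr(res.params, "iloc") else res.params[-1])
    theta = np.inf if alpha <= 0 else 1.0 / alpha
    return _wrap("negbin_glm", res, converged=converged,
                 extra={"alpha": alpha, "theta": theta})


def fit_sqrt_lm(rates, design) -> ModelFit:
    """Ordinary linear model of sqrt(rate) on the predictors; reports R^2."""
    rates = np.asarray(rates, dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0 before the square-root transform")
    X = _as_design(design)
    res = sm.OLS(np.sqrt(rates), X).fit()
    extra: dict = {"r2": float(res.rsquared)}
    if np.ptp(np.sqrt(rates)) == 0:
        extra["flag"] = "constant response: R^2 undefined"
        extra["r2"] = 0.0
    return _wrap("sqrt_lm", res, converged=True, extra=extra)
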