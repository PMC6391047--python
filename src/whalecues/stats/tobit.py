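"""Tobit (censored Gaussian) regression.

Zone residence times are zero-inflated: many whale groups never enter the
exposure zone, producing a point mass at 0 minutes, while entries produce a
continuous positive response.  The Tobit model treats the observed response
as a latent Gaussian ``y* = X b + e``, ``e ~ N(0, sigma^2)``, censored below
at ``left`` (default 0) and optionally above at ``right`` (the trial length).
The log-likelihood mixes a probit mass at each bound with the Gaussian
density in the interior:

    ll = sum_unc [ log phi((y - Xb)/s) - log s ]
       + sum_left  log Phi((L - Xb)/s)
       + sum_right log (1 - Phi((U - Xb)/s))

Estimation is maximum likelihood with analytic score; standard errors come
from the numerical observed information.  The internal scale parameter is
``ln sigma`` so the optimisation is unconstrained.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.base.model import GenericLikelihoodModel

__all__ = ["Tobit"]


class Tobit(GenericLikelihoodModel):
    """Censored Gaussian regression, statsmodels-style.

    Parameters
    ----------
    endog : array
        Observed (censored) response.
    exog : array
        Design matrix including the constant.
    left : float or None
        Lower censoring bound (default 0); None disables it.
    right : float or None
        Upper censoring bound (default None); set to the trial length to
        right-censor groups present throughout.

    ``fit()`` returns a results object with ``params`` (slopes followed by
    ``ln_sigma``), ``bse``, ``conf_int()``, ``llf``, ``aic``, a ``summary()``
    table, plus ``sigma``, ``converged`` and ``mcfadden_r2`` attributes.
    """

    def __init__(self, endog, exog, left: float | None = 0.0,
                 right: float | None = None, **kwargs):
        super().__init__(endog, exog, **kwargs)
        if left is not None and right is not None and not left < right:
            raise ValueError("left bound must lie below right bound")
        self.left = left
        self.right = right
        self._set_extra_params_names(["ln_sigma"])
        y = self.endog
        self._cens_left = (y <= left) if left is not None else np.zeros(y.size, bool)
        self._cens_right = (y >= right) if right is not None else np.zeros(y.size, bool)
        self._uncens = ~(self._cens_left | self._cens_right)
        if not self._uncens.any():
            raise ValueError("degenerate likelihood: all observations censored")
        if np.ptp(y[self._uncens]) == 0 and not (self._cens_left.any() or self._cens_right.any()):
            raise ValueError("degenerate input: constant uncensored response (sigma -> 0)")

    # -- likelihood ---------------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        beta, sigma = params[:-1], np.exp(params[-1])
        xb = self.exog @ beta
        y = self.endog
        ll = 0.0
        u = self._uncens
        if u.any():
            z = (y[u] - xb[u]) / sigma
            ll += float(np.sum(stats.norm.logpdf(z) - np.log(sigma)))
        if self._cens_left.any():
            a = (self.left - xb[self._cens_left]) / sigma
            ll += float(np.sum(stats.norm.logcdf(a)))
        if self._cens_right.any():
            b = (self.right - xb[self._cens_right]) / sigma
            ll += float(np.sum(stats.norm.logsf(b)))
        return ll

    def score(self, params: np.ndarray) -> np.ndarray:
        beta, sigma = params[:-1], np.exp(params[-1])
        xb = self.exog @ beta
        y = self.endog
        g_beta = np.zeros(beta.size)
        g_lns = 0.0
        u = self._uncens
        if u.any():
            z = (y[u] - xb[u]) / sigma
            g_beta += self.exog[u].T @ (z / sigma)
            g_lns += float(np.sum(z**2 - 1.0))
        if self._cens_left.any():
            a = (self.left - xb[self._cens_left]) / sigma
            lam = np.exp(stats.norm.logpdf(a) - stats.norm.logcdf(a))
            g_beta += self.exog[self._cens_left].T @ (-lam / sigma)
            g_lns += float(np.sum(-a * lam))
        if self._cens_right.any():
            b = (self.right - xb[self._cens_right]) / sigma
            mu = np.exp(stats.norm.logpdf(b) - stats.norm.logsf(b))
            g_beta += self.exog[self._cens_right].T @ (mu / sigma)
            g_lns += float(np.sum(b * mu))
        return np.append(g_beta, g_lns)

    def hessian(self, params: np.ndarray) -> np.ndarray:
        # centered differentiation of the analytic score: markedly more
        # accurate than second differences of the likelihood itself, which
        # inflate the Wald standard errors
        from statsmodels.tools.numdiff import approx_fprime

        H = approx_fprime(params, self.score, centered=True)
        return (H + H.T) / 2.0

    # -- fitting ------------------------------------------------------------

    def _start_params(self) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        resid = self.endog - self.exog @ beta
        sigma = max(float(resid.std()), 1e-3)
        return np.append(beta, np.log(sigma))

    def fit(self, start_params=None, method: str = "bfgs", maxiter: int = 500,
            disp: bool = False, compute_pseudo_r2: bool = True, **kwargs):
        if start_params is None:
            start_params = self._start_params()
        res = super().fit(start_params=start_params, method=method,
                          maxiter=maxiter, disp=disp, gtol=kwargs.pop("gtol", 1e-8),
                          **kwargs)
        # BFGS may report failure on badly scaled designs even at the optimum;
        # trust the actual score norm, scaled by the likelihood magnitude
        gnorm = float(np.max(np.abs(self.score(res.params))))
        res.converged = bool(
            res.mle_retvals.get("converged", False)
            or gnorm <= 1e-5 * (1.0 + abs(res.llf))
        )
        res.score_norm = gnorm
        res.sigma = float(np.exp(res.params[-1]))
        res.n_censored_left = int(self._cens_left.sum())
        res.n_censored_right = int(self._cens_right.sum())
        if compute_pseudo_r2:
            if self.exog.shape[1] == 1 and np.ptp(self.exog) == 0:
                res.mcfadden_r2 = 0.0
            else:
                null = Tobit(self.endog, np.ones((self.endog.size, 1)),
                             left=self.left, right=self.right)
                llf0 = null.fit(compute_pseudo_r2=False).llf
                res.llf_null = float(llf0)
                res.mcfadden_r2 = float(1.0 - res.llf / llf0) if llf0 != 0 else np.nan
        return res
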