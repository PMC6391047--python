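"""Post-hoc contrasts on fitted models (stimulus vs. control comparisons).

Each contrast row c tests ``c' beta = 0`` with a Wald z statistic
``z = c' beta / sqrt(c' V c)``.  Family-wise adjustment is Bonferroni by
default; the single-step method (the multivariate-normal max-|z| adjustment
used by multiple-comparison procedures on GLMs) is available as an option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["posthoc_contrasts"]


def _params_cov(fit) -> tuple[np.ndarray, np.ndarray]:
    params = np.asarray(fit.params, dtype=np.float64)
    cov = np.asarray(fit.cov_params(), dtype=np.float64)
    return params, cov


def posthoc_contrasts(
    fit,
    contrasts,
    method: str = "bonferroni",
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Wald z tests with family-wise adjusted p-values for a contrast matrix.

    ``fit`` is any results object exposing ``params`` and ``cov_params()``
    (this package's ModelFit, a Tobit results object, or a raw statsmodels
    fit).  ``contrasts`` is an (m x k) matrix conformable with the
    coefficient vector; it must have full row rank.
    """
    params, cov = _params_cov(fit)
    C = np.atleast_2d(np.asarray(contrasts, dtype=np.float64))
    if C.shape[1] != params.size:
        raise ValueError(
            f"contrast matrix has {C.shape[1]} columns but the model has "
            f"{params.size} coefficients"
        )
    if np.linalg.matrix_rank(C) < C.shape[0]:
        raise ValueError("contrast matrix is rank-deficient")
    est = C @ params
    V = C @ cov @ C.T
    se = np.sqrt(np.diag(V))
    z = est / se
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    m = C.shape[0]
    if method == "bonferroni":
        p_adj = np.minimum(1.0, m * p_raw)
    elif method == "single-step":
        # P(max |Z| >= |z_i|) under the joint normal of the contrast estimates
        R = V / np.outer(se, se)
        mvn = stats.multivariate_normal(mean=np.zeros(m), cov=R, allow_singular=True)
        p_adj = np.array(
            [1.0 - mvn.cdf(np.full(m, abs(zi)), lower_limit=np.full(m, -abs(zi)))
             for zi in z]
        )
        p_adj = np.clip(p_adj, p_raw, 1.0)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return pd.DataFrame(
        {"estimate": est, "se": se, "z": z, "p_raw": p_raw, "p_adj": p_adj},
        index=names if names is not None else range(m),
    )
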