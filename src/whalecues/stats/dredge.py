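"""Exhaustive AIC model selection over predictor subsets.

Mirrors the all-subsets "dredge" workflow: fit every subset of the candidate
predictors (2^p models, p <= 12), rank by AIC, and report ΔAIC relative to
the best model.  A model is flagged substantially better than the runner-up
when its AIC is lower by at least 2 units.
"""

from __future__ import annotations

from itertools import combinations
from typing import Callable, Sequence

import pandas as pd

__all__ = ["dredge_aic"]


def dredge_aic(
    data: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    fitter: Callable[[str, pd.DataFrame], object],
    always: Sequence[str] = (),
) -> pd.DataFrame:
    """Fit every predictor subset and rank by AIC.

    Parameters
    ----------
    data : DataFrame
        One row per sampling unit, holding the response and all predictors.
    response : str
        Response column name.
    predictors : sequence of str
        Candidate predictor terms (formula fragments; at most 12).
    fitter : callable
        ``fitter(formula, data)`` returning an object with an ``aic``
        attribute (any of this package's fitters wrapped accordingly, or a
        statsmodels formula fit).
    always : sequence of str
        Terms included in every candidate model.

    Returns
    -------
    DataFrame with one row per candidate, ranked by AIC: inclusion flags per
    predictor, ``k`` (number of terms), ``aic``, ``delta_aic``, an ``error``
    column for failed fits (never dropped silently), and
    ``substantially_better`` — true for the best model iff it beats the
    runner-up by >= 2 AIC units.
    """
    predictors = list(predictors)
    if len(predictors) > 12:
        raise ValueError(f"at most 12 candidate predictors ({len(predictors)} given)")
    rows = []
    for r in range(len(predictors) + 1):
        for subset in combinations(predictors, r):
            terms = list(always) + list(subset)
            formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
            row: dict = {p: p in subset for p in predictors}
            row["formula"] = formula
            row["k"] = len(terms)
            try:
                fit = fitter(formula, data)
                row["aic"] = float(fit.aic)
                row["error"] = ""
            except Exception as exc:  # recorded, not dropped
                row["aic"] = float("nan")
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values("aic", na_position="last", kind="stable").reset_index(drop=True)
    best = table["aic"].min()
    table["delta_aic"] = table["aic"] - best
    table["substantially_better"] = False
    ok = table["aic"].notna()
    if ok.sum() >= 2:
        runner_up_delta = table.loc[ok, "delta_aic"].iloc[1]
        table.loc[0, "substantially_better"] = bool(runner_up_delta >= 2.0)
    return table
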