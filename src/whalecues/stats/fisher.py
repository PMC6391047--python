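"""Two-sided Fisher exact test for 2x2 occurrence tables.

The two-sided rule is the probability-mass ("minimum-likelihood") convention:
with both margins fixed, sum the hypergeometric probabilities of every table
whose probability does not exceed that of the observed table (with a small
relative slack to absorb floating-point ties).  This is the convention used
by the major statistical environments, stated explicitly here because
two-sided conventions for exact tests differ.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import hypergeom

__all__ = ["fisher_exact_2x2"]

#: relative slack when comparing table probabilities (floating-point ties)
_SLACK = 1e-7


def fisher_exact_2x2(table) -> float:
    """Two-sided exact p for a 2x2 contingency table ``[[a, b], [c, d]]``.

    Rows are the two groups (e.g. stimulus vs. control), columns the
    displayed / not-displayed counts.  If a margin is empty the test carries
    no information and p = 1 is returned with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table entries must be non-negative integers")
    t = t.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("empty margin: Fisher exact test is uninformative, p = 1")
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = hypergeom.pmf(k, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    p = float(probs[probs <= p_obs * (1.0 + _SLACK)].sum())
    return min(p, 1.0)
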