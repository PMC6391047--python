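"""Repertoire clustering and its information-theoretic evaluation.

Descriptor vectors are z-scored, embedded in 2-D with t-SNE, and clustered
with a truncated variational Dirichlet-process Gaussian mixture (a Bayesian
nonparametric mixture: the effective number of clusters is inferred from the
data rather than fixed).  Correspondence between the acoustic clusters X and
the stimulus conditions Y is scored by normalized mutual information,

    NMI(X, Y) = I(X, Y) / sqrt(H(X) * H(Y)),

computed from the empirical joint distribution with entropies in bits.  NMI
is 0 when the partitions are independent and 1 at one-to-one correspondence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE
from sklearn.mixture import BayesianGaussianMixture

__all__ = ["ClusterEvaluation", "embed_2d", "fit_bnp", "nmi", "scan_clusters"]

logger = logging.getLogger(__name__)


@dataclass
class ClusterEvaluation:
    """Entropies, mutual information and NMI of a (clusters, conditions) pair."""

    h_x: float  # entropy of the cluster labels, bits
    h_y: float  # entropy of the condition labels, bits
    mi: float  # mutual information, bits
    nmi: float  # in [0, 1]
    n_clusters: int
    n: int


def _as_codes(labels) -> np.ndarray:
    return pd.factorize(np.asarray(labels))[0]


def nmi(x, y, average: str = "geometric") -> ClusterEvaluation:
    """Normalized mutual information between two labelings.

    Entropies and MI are computed in bits from the empirical contingency
    table.  ``average`` selects the normalization: ``"geometric"`` (default,
    ``I/sqrt(Hx*Hy)``) or ``"arithmetic"`` (``2I/(Hx+Hy)``).  If either
    entropy is zero the score is defined as 1 when the two partitions are
    identical as set partitions and 0 otherwise.
    """
    x = _as_codes(x)
    y = _as_codes(y)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise ValueError("empty labelings")
    n = x.size
    joint = np.zeros((x.max() + 1, y.max() + 1))
    np.add.at(joint, (x, y), 1.0)
    p = joint / n
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def _h(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    h_x, h_y = _h(px), _h(py)
    nz = p > 0
    mi = float((p[nz] * np.log2(p[nz] / np.outer(px, py)[nz])).sum())
    mi = max(mi, 0.0)

    if h_x == 0.0 or h_y == 0.0:
        # a constant labeling carries no information; identical partitions
        # (both constant) count as perfect correspondence
        score = 1.0 if h_x == h_y == 0.0 else 0.0
    elif average == "geometric":
        score = mi / np.sqrt(h_x * h_y)
    elif average == "arithmetic":
        score = 2.0 * mi / (h_x + h_y)
    else:
        raise ValueError(f"unknown average {average!r}")
    return ClusterEvaluation(
        h_x=h_x, h_y=h_y, mi=mi, nmi=float(min(score, 1.0)),
        n_clusters=int(np.unique(x).size), n=n,
    )


def embed_2d(
    descriptors: np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """Z-score the descriptor matrix and embed it in 2-D with t-SNE.

    t-SNE is preferred over PCA here because relations among contour
    descriptors (frequency statistics vs. their derivatives) are nonlinear.
    Deterministic for a fixed seed.  Requires ``n > 3 * perplexity``.
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D matrix")
    bad = np.nonzero(~np.isfinite(X).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite descriptors in rows {bad.tolist()[:20]}")
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(f"need n > 3*perplexity = {3 * perplexity:.0f}, got {n}")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    )
    return tsne.fit_transform(Z)


def fit_bnp(
    coords: np.ndarray,
    concentration: float = 1.0,
    truncation: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Dirichlet-process Gaussian-mixture labels for 2-D coordinates.

    Inference is variational on a truncated stick-breaking representation
    (``truncation`` components, concentration = DP scale).  The effective
    number of clusters is the number of components holding at least one
    point, always <= truncation.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need an (n >= 2) x d coordinate matrix")
    if np.allclose(coords, coords[0]):
        warnings.warn("degenerate (all-identical) coordinates: single cluster")
        return np.zeros(coords.shape[0], dtype=int)
    bgm = BayesianGaussianMixture(
        n_components=truncation,
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=concentration,
        covariance_type="full",
        max_iter=500,
        random_state=seed,
    )
    labels = bgm.fit_predict(coords)
    return np.asarray(labels, dtype=int)


def scan_clusters(
    descriptors: np.ndarray,
    conditions,
    concentrations: tuple[float, ...] = (0.1, 1.0, 10.0),
    truncations: tuple[int, ...] = (10,),
    perplexity: float = 30.0,
    n_replicates: int = 5,
    seed: int = 0,
) -> tuple[ClusterEvaluation, np.ndarray, pd.DataFrame]:
    """Grid search over mixture settings for the maximum-NMI clustering.

    Embeds once per seed, then fits the DP mixture for every (concentration,
    truncation) setting, ``n_replicates`` restarts each, and scores every fit
    against the condition labels.  Returns the best evaluation, its labels,
    and the full score table (setting, replicate, n_clusters, NMI).
    """
    y = np.asarray(conditions)
    n_settings = len(concentrations) * len(truncations)
    if n_settings < 2 and n_replicates < 2:
        raise ValueError("need at least 2 candidate settings or replicates")
    coords = embed_2d(descriptors, perplexity=perplexity, seed=seed)

    records = []
    best: tuple[ClusterEvaluation, np.ndarray] | None = None
    for conc in concentrations:
        for trunc in truncations:
            for rep in range(n_replicates):
                labels = fit_bnp(coords, concentration=conc, truncation=trunc,
                                 seed=seed + 1000 * rep)
                ev = nmi(labels, y)
                records.append(
                    {"concentration": conc, "truncation": trunc, "replicate": rep,
                     "n_clusters": ev.n_clusters, "nmi": ev.nmi}
                )
                if best is None or ev.nmi > best[0].nmi:
                    best = (ev, labels)
    table = pd.DataFrame(records)
    assert best is not None
    logger.info("scan_clusters: best NMI %.3f with %d clusters",
                best[0].nmi, best[0].n_clusters)
    return best[0], best[1], table
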