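"""Rao quadratic-entropy diversity partitioning.

Rao's quadratic entropy Q = sum_ij d_ij p_i p_j is the expected
dissimilarity between two individuals drawn at random (with replacement)
from a community with relative abundances p and species dissimilarities
d.  With unit dissimilarities between distinct species it reduces to the
Gini-Simpson index (the taxonomic facet, TD); with patristic distances it
measures phylogenetic diversity (PD).

Two optional corrections are provided, both on by default through the
``corrected`` flag:

* alpha/gamma values are expressed as equivalent numbers 1 / (1 - Q)
  after rescaling dissimilarities to [0, 1] by the regional maximum —
  the number of equally abundant, maximally distinct species yielding
  the same entropy;
* pairwise multiplicative beta, beta = (gamma_pair - alpha_mean) /
  gamma_pair * 100, is divided by its theoretical two-community maximum
  (1 - 1/N with N = 2, i.e. multiplied by 2) when computed from
  equivalent numbers.

Communities are plots x species count tables (pandas DataFrames);
dissimilarities are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "taxonomic_distances",
    "rao_entropy",
    "equivalent_numbers",
    "alpha_profile",
    "pairwise_beta",
    "mpd",
    "read_community_csv",
    "BetaResult",
]


def taxonomic_distances(species) -> DistanceMatrix:
    """Unit dissimilarities: d_ij = 1 for i != j, 0 on the diagonal.

    Rao entropy computed with this matrix equals the Gini-Simpson index
    1 - sum(p_i^2).
    """
    species = list(species)
    n = len(species)
    if n < 1:
        raise ValueError("need at least one species")
    vals = np.ones((n, n)) - np.eye(n)
    return DistanceMatrix(vals, ids=species)


def _check_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a vector")
    if np.any(p < 0):
        raise ValueError("relative abundances must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(
            f"relative abundances must sum to 1 (got {p.sum()!r}); "
            "normalization is the caller's explicit step"
        )
    return p


def rao_entropy(p, D: DistanceMatrix | np.ndarray) -> float:
    """Rao quadratic entropy Q = sum_ij d_ij p_i p_j."""
    p = _check_p(p)
    dvals = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    if len(p) != dvals.shape[0]:
        raise ValueError(
            f"length of p ({len(p)}) != matrix size ({dvals.shape[0]})"
        )
    return float(p @ dvals @ p)


def equivalent_numbers(raw_q: float) -> float:
    """Equivalent-number transform 1 / (1 - Q) of a Rao entropy computed
    on dissimilarities rescaled to [0, 1]."""
    q = float(raw_q)
    if q < 0 or q >= 1:
        raise ValueError(
            f"raw_q must lie in [0, 1) after rescaling dissimilarities "
            f"(got {q})"
        )
    return 1.0 / (1.0 - q)


def _align(cm: pd.DataFrame, D: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return (counts array aligned to D's species order restricted to the
    community's species, distance sub-matrix)."""
    species = list(cm.columns)
    missing = sorted(set(species) - set(D.ids))
    if missing:
        raise ValueError(
            f"species in community table missing from distance matrix: "
            f"{missing}"
        )
    sub = D.filter(species).data
    counts = cm.to_numpy(dtype=float)
    return counts, sub


def _rao_rows(P: np.ndarray, dvals: np.ndarray) -> np.ndarray:
    """Row-wise Rao entropy for a matrix of relative-abundance rows."""
    return np.einsum("ps,st,pt->p", P, dvals, P, optimize=True)


def alpha_profile(
    cm: pd.DataFrame,
    D: DistanceMatrix,
    corrected: bool = True,
) -> pd.DataFrame:
    """Per-plot alpha diversity.

    Returns a DataFrame indexed by plot with columns ``raw_q`` (Rao
    entropy on the supplied dissimilarities), ``corrected`` (equivalent
    numbers on dissimilarities rescaled by the regional maximum; NaN if
    ``corrected`` is False) and ``n_species``.
    """
    counts, sub = _align(cm, D)
    rowsum = counts.sum(axis=1)
    empty = cm.index[rowsum == 0].tolist()
    if empty:
        raise ValueError(f"plots with empty rows: {empty}")
    P = counts / rowsum[:, None]
    raw = _rao_rows(P, sub)
    out = pd.DataFrame(
        {
            "raw_q": raw,
            "n_species": (counts > 0).sum(axis=1),
        },
        index=cm.index,
    )
    if corrected:
        dmax = sub.max()
        if dmax > 0:
            q01 = raw / dmax
        else:
            q01 = raw  # single species: raw is 0 anyway
        out["corrected"] = np.array([equivalent_numbers(q) for q in q01])
    else:
        out["corrected"] = np.nan
    return out


@dataclass
class BetaResult:
    """Pairwise multiplicative beta-diversity matrix with metadata."""

    matrix: DistanceMatrix
    corrected: bool
    pooling: str


def pooled_pair_counts(counts: np.ndarray, pooling: str = "counts") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled relative-abundance rows for every plot pair.

    Returns (pairs_i, pairs_j, pooled P matrix of shape n_pairs x S).
    ``pooling='counts'`` sums raw counts then renormalizes (plots
    weighted by sampling effort); ``pooling='equal'`` averages the two
    plots' relative-abundance vectors.
    """
    n = counts.shape[0]
    ii, jj = np.triu_indices(n, k=1)
    if pooling == "counts":
        pooled = counts[ii] + counts[jj]
    elif pooling == "equal":
        rowsum = counts.sum(axis=1, keepdims=True)
        P = counts / rowsum
        pooled = (P[ii] + P[jj]) / 2.0
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    pooled = pooled / pooled.sum(axis=1, keepdims=True)
    return ii, jj, pooled


def beta_from_components(gamma_pair, alpha_i, alpha_j, corrected: bool) -> np.ndarray:
    """Multiplicative pairwise beta (percent) from gamma and alpha values.

    Inputs are raw Rao entropies on [0,1]-rescaled dissimilarities when
    ``corrected``; the equivalent-number transform and the two-community
    maximum correction (x2) are then applied before the x100 scaling.
    """
    gamma_pair = np.asarray(gamma_pair, float)
    alpha_i = np.asarray(alpha_i, float)
    alpha_j = np.asarray(alpha_j, float)
    if corrected:
        g = 1.0 / (1.0 - gamma_pair)
        a = (1.0 / (1.0 - alpha_i) + 1.0 / (1.0 - alpha_j)) / 2.0
        prop = np.where(g > 0, (g - a) / np.where(g > 0, g, 1.0), 0.0)
        beta = prop * 2.0 * 100.0
    else:
        a = (alpha_i + alpha_j) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            prop = np.where(gamma_pair > 0, (gamma_pair - a) / np.where(gamma_pair > 0, gamma_pair, 1.0), 0.0)
        beta = prop * 100.0
    return beta


def pairwise_beta(
    cm: pd.DataFrame,
    D: DistanceMatrix,
    corrected: bool = True,
    pooling: str = "counts",
) -> BetaResult:
    """Pairwise multiplicative beta-diversity between all plot pairs.

    beta = (gamma_pair - alpha_mean) / gamma_pair * 100, where
    gamma_pair is the Rao entropy of the pooled pair and alpha_mean the
    mean of the two plot entropies.  With ``corrected`` the components
    are transformed to equivalent numbers (on [0,1]-rescaled
    dissimilarities) and beta is divided by its two-community maximum.
    """
    if cm.shape[0] < 2:
        raise ValueError("need at least two plots for pairwise beta")
    counts, sub = _align(cm, D)
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("plots with empty rows cannot enter beta")
    dvals = sub
    if corrected:
        dmax = dvals.max()
        if dmax > 0:
            dvals = dvals / dmax
    P = counts / counts.sum(axis=1, keepdims=True)
    alpha = _rao_rows(P, dvals)
    ii, jj, pooled = pooled_pair_counts(counts, pooling)
    gamma = _rao_rows(pooled, dvals)
    degenerate = gamma == 0 if not corrected else np.zeros(len(gamma), bool)
    if not corrected and degenerate.any():
        logger.info(
            "%d plot pairs with gamma_pair = 0; beta set to 0",
            int(degenerate.sum()),
        )
    beta = beta_from_components(gamma, alpha[ii], alpha[jj], corrected)
    n = cm.shape[0]
    mat = np.zeros((n, n))
    mat[ii, jj] = beta
    mat[jj, ii] = beta
    dm = DistanceMatrix(mat, ids=[str(p) for p in cm.index])
    return BetaResult(matrix=dm, corrected=corrected, pooling=pooling)


def mpd(p, D: DistanceMatrix | np.ndarray) -> float:
    """Abundance-weighted mean pairwise distance:
    sum_{i!=j} d_ij p_i p_j / sum_{i!=j} p_i p_j."""
    p = np.asarray(p, dtype=float)
    dvals = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    if (p > 0).sum() < 2:
        raise ValueError("MPD undefined for fewer than two species present")
    num = p @ dvals @ p
    den = p.sum() ** 2 - (p**2).sum()
    return float(num / den)


def read_community_csv(path) -> pd.DataFrame:
    """Read a plots x species count table (first column = plot ID)."""
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("community counts must be non-negative")
    return df
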