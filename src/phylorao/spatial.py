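"""Landscape-scale beta-diversity statistics.

Simple and partial Mantel tests (permutation of one matrix's rows and
columns), PCNM spatial eigenvectors (PCoA of a truncated inter-plot
distance matrix), double-stop forward selection on an RDA, distance-based
redundancy analysis with Ezekiel-adjusted R-squared, and three-set
variation partitioning (disturbance / loss / space) by inclusion-
exclusion over the seven marginal db-RDA models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from skbio import DistanceMatrix

__all__ = [
    "PCNMBasis",
    "VariationPartition",
    "euclidean_plot_distances",
    "mantel",
    "partial_mantel",
    "pcnm_basis",
    "forward_select",
    "dbrda_r2",
    "ezekiel_adjusted_r2",
    "pcoa_coordinates",
    "variation_partition",
    "gradient_distance",
]


@dataclass
class PCNMBasis:
    eigenvectors: pd.DataFrame   # plots x axes, unit-norm columns
    eigenvalues: np.ndarray      # positive eigenvalues, descending
    truncation: float

    @property
    def n_axes(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class VariationPartition:
    fractions: dict              # a,b,c,d,e,f,g,residual (adjusted R^2)
    tests: dict                  # p-values for testable fractions
    notes: list = field(default_factory=list)


def euclidean_plot_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between plots from easting/northing
    coordinates (metres).  Duplicate coordinates are allowed."""
    if coords.shape[0] < 2:
        raise ValueError("need at least two plots")
    xy = coords[["easting", "northing"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    vals = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(vals, ids=[str(p) for p in coords.index])


def gradient_distance(values: pd.Series | np.ndarray, ids=None) -> DistanceMatrix:
    """Distance matrix of absolute differences of a plot-level gradient
    (e.g. |disturbance_i - disturbance_j|)."""
    if isinstance(values, pd.Series):
        ids = [str(i) for i in values.index] if ids is None else ids
        values = values.to_numpy(dtype=float)
    values = np.asarray(values, float)
    vals = np.abs(values[:, None] - values[None, :])
    if ids is None:
        ids = [str(i) for i in range(len(values))]
    return DistanceMatrix(vals, ids=ids)


def _tri(values: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(values.shape[0], k=1)
    return values[i, j]


def _as_values(dm) -> np.ndarray:
    if isinstance(dm, DistanceMatrix):
        return dm.data
    return np.asarray(dm, dtype=float)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        raise ValueError("zero variance in a distance-matrix triangle")
    return float((a @ b) / den)


def _perm_p(null: np.ndarray, observed: float, alternative: str) -> float:
    if alternative == "greater":
        extreme = np.sum(null >= observed)
    elif alternative == "two-sided":
        extreme = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((extreme + 1) / (len(null) + 1))


def mantel(
    A,
    B,
    n_perm: int = 999,
    alternative: str = "greater",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson correlation of the vectorized lower triangles,
    with significance from random row/column permutations of A."""
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(rng)
    av, bv = _as_values(A), _as_values(B)
    if av.shape != bv.shape:
        raise ValueError("distance matrices must have the same shape")
    a, b = _tri(av), _tri(bv)
    r_obs = _pearson(a, b)
    n = av.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = _pearson(_tri(av[np.ix_(perm, perm)]), b)
    return r_obs, _perm_p(null, r_obs, alternative)


def _partial_r(rab: float, rac: float, rbc: float) -> float:
    den = np.sqrt((1 - rac**2) * (1 - rbc**2))
    if den == 0:
        raise ValueError("degenerate conditioning: |r| = 1 with the covariate")
    return (rab - rac * rbc) / den


def partial_mantel(
    A,
    B,
    C,
    n_perm: int = 999,
    alternative: str = "greater",
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Partial Mantel test of A ~ B conditioned on C.

    r_AB|C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2)); the
    permutation distribution permutes A's rows/columns with B and C held
    fixed, recomputing the partial statistic.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(rng)
    av, bv, cv = _as_values(A), _as_values(B), _as_values(C)
    if not (av.shape == bv.shape == cv.shape):
        raise ValueError("distance matrices must have the same shape")
    a, b, c = _tri(av), _tri(bv), _tri(cv)
    rbc = _pearson(b, c)
    if abs(rbc) >= 1 - 1e-12:
        raise ValueError("degenerate conditioning: |r_BC| = 1")
    r_obs = _partial_r(_pearson(a, b), _pearson(a, c), rbc)
    n = av.shape[0]
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        ap = _tri(av[np.ix_(perm, perm)])
        null[k] = _partial_r(_pearson(ap, b), _pearson(ap, c), rbc)
    return r_obs, _perm_p(null, r_obs, alternative)


def _gower_center(sq: np.ndarray) -> np.ndarray:
    A = -0.5 * sq
    row = A.mean(axis=0)
    return A - row[None, :] - row[:, None] + A.mean()


def pcnm_basis(D, truncation: float | None = None) -> PCNMBasis:
    """PCNM spatial eigenvectors.

    Distances above the truncation threshold (by default the longest edge
    of the minimum spanning tree) are replaced by 4x the threshold; the
    positive-eigenvalue eigenvectors of the PCoA of the modified matrix
    are returned with unit norm, ordered by eigenvalue.
    """
    vals = _as_values(D)
    ids = list(D.ids) if isinstance(D, DistanceMatrix) else [
        str(i) for i in range(vals.shape[0])
    ]
    n = vals.shape[0]
    if n < 3:
        raise ValueError("PCNM needs at least three plots")
    if vals[np.triu_indices(n, 1)].max() == 0:
        raise ValueError("all plots have identical coordinates")
    if truncation is None:
        mst = minimum_spanning_tree(vals).toarray()
        truncation = float(mst.max())
    W = vals.copy()
    W[W > truncation] = 4.0 * truncation
    G = _gower_center(W**2)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = np.abs(eigval).max() * 1e-8
    keep = eigval > tol
    vecs = eigvec[:, keep]
    # deterministic sign: largest-magnitude element positive
    for k in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, k]))
        if vecs[j, k] < 0:
            vecs[:, k] *= -1
    cols = [f"PCNM{i+1}" for i in range(vecs.shape[1])]
    return PCNMBasis(
        eigenvectors=pd.DataFrame(vecs, index=ids, columns=cols),
        eigenvalues=eigval[keep],
        truncation=truncation,
    )


def _rda_r2(Yc: np.ndarray, X: np.ndarray) -> float:
    """Fraction of the (centered) response inertia explained by the
    column space of centered X."""
    if X.size == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    Q, R = np.linalg.qr(Xc)
    rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max()))
    Q = Q[:, :rank]
    fitted = Q @ (Q.T @ Yc)
    tot = float((Yc**2).sum())
    return float((fitted**2).sum()) / tot


def ezekiel_adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if p >= n - 1:
        raise ValueError(f"p = {p} >= n - 1 = {n - 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def pcoa_coordinates(dm, correction: str = "lingoes") -> np.ndarray:
    """Principal-coordinate embedding of a dissimilarity matrix.

    Negative eigenvalues are handled by the Lingoes constant correction
    (default), by taking square roots of the dissimilarities, or dropped
    (``correction='none'``).
    """
    vals = _as_values(dm).astype(float)
    if correction == "sqrt":
        vals = np.sqrt(vals)
    G = _gower_center(vals**2)
    eigval, eigvec = np.linalg.eigh(G)
    tol = max(np.abs(eigval).max(), 1.0) * 1e-10
    if correction == "lingoes" and eigval.min() < -tol:
        c1 = -eigval.min()
        sq = vals**2 + 2.0 * c1
        np.fill_diagonal(sq, 0.0)
        G = _gower_center(sq)
        eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > tol
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _as_X(X) -> np.ndarray:
    if X is None:
        return np.empty((0, 0))
    if isinstance(X, (pd.DataFrame, pd.Series)):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def dbrda_r2(beta, X, correction: str = "lingoes") -> tuple[float, float]:
    """Distance-based RDA of a beta-diversity matrix on predictors X.

    Returns (R^2, Ezekiel-adjusted R^2), where R^2 is the fraction of the
    principal-coordinate inertia explained by X.
    """
    from .diversity import BetaResult

    if isinstance(beta, BetaResult):
        beta = beta.matrix
    Y = pcoa_coordinates(beta, correction)
    Yc = Y - Y.mean(axis=0)
    X = _as_X(X)
    n = Y.shape[0]
    if X.shape[0] not in (0, n):
        raise ValueError("predictor rows do not match plots")
    p = X.shape[1]
    if p >= n - 1:
        raise ValueError(f"too many predictors (p = {p}, n = {n})")
    r2 = _rda_r2(Yc, X)
    return r2, ezekiel_adjusted_r2(r2, n, p)


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.050,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
) -> list:
    """Double-stop forward selection of RDA predictors.

    Starts only if the full-candidate model is itself significant.  At
    each step the candidate adding the most explained variance is tested
    by permutation (the added R^2 under row permutations of the current
    residuals); selection stops when that p-value exceeds *alpha* or
    when the cumulative adjusted R^2 of the already-selected model
    reaches the full model's adjusted R^2 (the double stop).  The
    ceiling is applied to the selected model, not to the candidate
    model: with few plots the expected adjusted R^2 of the full model
    lies at or below that of the true predictor subset, so a
    candidate-model ceiling would systematically reject genuine
    predictors.  May return an empty list.
    """
    rng = np.random.default_rng(rng)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    Yc = Y - Y.mean(axis=0)
    n = Yc.shape[0]
    names = list(candidates.columns)
    Xall = candidates.to_numpy(dtype=float)
    if not names:
        return []

    # global significance gate
    r2_full = _rda_r2(Yc, Xall)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _rda_r2(Yc[rng.permutation(n)], Xall)
    if _perm_p(null, r2_full, "greater") > alpha:
        return []
    adj_full = ezekiel_adjusted_r2(r2_full, n, Xall.shape[1])

    selected: list = []
    remaining = list(names)
    r2_sel = 0.0
    while remaining:
        if selected:
            adj_sel = ezekiel_adjusted_r2(r2_sel, n, len(selected))
            if adj_sel >= adj_full - 1e-12:
                break
        added = []
        for name in remaining:
            cols = selected + [name]
            r2 = _rda_r2(Yc, candidates[cols].to_numpy(dtype=float))
            added.append(r2 - r2_sel)
        best_i = int(np.argmax(added))
        best = remaining[best_i]
        cols = selected + [best]
        r2_new = r2_sel + added[best_i]

        # permutation test of the candidate's contribution, conditioning
        # on the already-selected predictors (residual permutation)
        if selected:
            Xs = candidates[selected].to_numpy(dtype=float)
            Xsc = Xs - Xs.mean(axis=0)
            Q, R = np.linalg.qr(Xsc)
            rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max()))
            Q = Q[:, :rank]
            resid = Yc - Q @ (Q.T @ Yc)
        else:
            resid = Yc
        stat_obs = added[best_i]
        Xnewcol = candidates[cols].to_numpy(dtype=float)
        null = np.empty(n_perm)
        for k in range(n_perm):
            Yp = (resid[rng.permutation(n)] + (Yc - resid))
            null[k] = _rda_r2(Yp, Xnewcol) - _rda_r2(
                Yp, Xnewcol[:, :-1] if selected else np.empty((n, 0))
            )
        p = _perm_p(null, stat_obs, "greater")
        if p > alpha:
            break
        if len(cols) >= n - 1:
            break
        selected.append(best)
        remaining.remove(best)
        r2_sel = r2_new
    return selected


def variation_partition(
    beta,
    disturbance,
    loss,
    space,
    n_perm: int = 999,
    rng: np.random.Generator | int | None = None,
    correction: str = "lingoes",
) -> VariationPartition:
    """Three-set variation partitioning of a beta-diversity matrix.

    Sets: 1 = disturbance, 2 = loss, 3 = selected spatial eigenvectors.
    The seven marginal db-RDA models are fitted, converted to adjusted
    R^2, and the Venn fractions solved by inclusion-exclusion:
    a, b, c are the unique fractions; d, e, f the pairwise joints;
    g the triple joint; residual = 1 - adj(all).  Unique fractions are
    tested by permutation of the residuals under the conditioning sets.
    An empty predictor set contributes zero fractions (noted).
    """
    from .diversity import BetaResult

    rng = np.random.default_rng(rng)
    if isinstance(beta, BetaResult):
        beta = beta.matrix
    Y = pcoa_coordinates(beta, correction)
    Yc = Y - Y.mean(axis=0)
    n = Yc.shape[0]

    X1, X2, X3 = _as_X(disturbance), _as_X(loss), _as_X(space)
    sets = {"1": X1, "2": X2, "3": X3}
    notes = []
    for key, X in sets.items():
        label = {"1": "disturbance", "2": "loss", "3": "space"}[key]
        if X.size == 0:
            notes.append(f"{label} set empty; its fractions are zero")

    def adj(keys: str) -> float:
        mats = [sets[k] for k in keys if sets[k].size]
        if not mats:
            return 0.0
        X = np.hstack(mats)
        r2 = _rda_r2(Yc, X)
        return ezekiel_adjusted_r2(r2, n, X.shape[1])

    A_, B_, C_ = adj("1"), adj("2"), adj("3")
    AB, AC, BC = adj("12"), adj("13"), adj("23")
    ABC = adj("123")

    a = ABC - BC
    b = ABC - AC
    c = ABC - AB
    dg = A_ + B_ - AB   # d + g
    eg = B_ + C_ - BC   # e + g
    fg = A_ + C_ - AC   # f + g
    g = (dg + eg + fg - ABC + a + b + c) / 2.0
    d = dg - g
    e = eg - g
    f = fg - g
    fractions = {
        "a": a, "b": b, "c": c, "d": d, "e": e, "f": f, "g": g,
        "residual": 1.0 - ABC,
    }

    def partial_test(target: np.ndarray, cond_keys: str) -> float:
        if target.size == 0:
            return float("nan")
        mats = [sets[k] for k in cond_keys if sets[k].size]
        if mats:
            Xc0 = np.hstack(mats)
            Xc0 = Xc0 - Xc0.mean(axis=0)
            Q, R = np.linalg.qr(Xc0)
            rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max()))
            Q = Q[:, :rank]
            resid = Yc - Q @ (Q.T @ Yc)
            fitted = Yc - resid
            r2_cond = _rda_r2(Yc, Xc0)
        else:
            resid, fitted, r2_cond = Yc, 0.0 * Yc, 0.0
        Xfull = np.hstack([m for m in (list(mats) + [target]) if m.size]) if mats else target
        stat_obs = _rda_r2(Yc, Xfull) - r2_cond
        null = np.empty(n_perm)
        for k in range(n_perm):
            Yp = fitted + resid[rng.permutation(n)]
            null[k] = _rda_r2(Yp, Xfull) - _rda_r2(Yp, Xc0) if mats else _rda_r2(Yp, Xfull)
        return _perm_p(null, stat_obs, "greater")

    tests = {
        "unique_disturbance": partial_test(X1, "23"),
        "unique_loss": partial_test(X2, "13"),
        "unique_space": partial_test(X3, "12"),
    }
    return VariationPartition(fractions=fractions, tests=tests, notes=notes)
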