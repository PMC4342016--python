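"""Tip-shuffle null models and standardized effect sizes (SES).

The null model permutes taxon labels across the tips of the regional
phylogeny — equivalently, co-permutes rows and columns of the regional
patristic distance matrix — leaving community abundances, per-plot
richness and the multiset of pairwise distances untouched.  Observed
alpha- and beta-diversity values are standardized against the null
distribution,

    SES = (OBS - mean(EXP)) / sd(EXP),

with the sample (n-1) standard deviation.  A plot (or pair) is
classified as overdispersed when fewer than ``alpha`` of the null values
are >= the observed value, underdispersed when fewer than ``alpha`` are
<= it, random otherwise, and undefined when the null standard deviation
is zero (e.g. a monospecific plot, whose entropy is zero under every
relabelling).

By default a single permutation stream is shared across all species
groups (all life stages see the same relabelling in a given iteration),
so cross-group comparisons are made against a common null; independent
per-group shuffles are available via ``shared_shuffle=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .diversity import _rao_rows, beta_from_components

__all__ = [
    "SESResult",
    "shuffle_tip_labels",
    "ses",
    "alpha_pd_ses",
    "beta_pd_ses",
    "mpd_ses",
    "dispersion_summary",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = ("overdispersed", "underdispersed", "random", "undefined")


@dataclass
class SESResult:
    target: object
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when undefined
    p_high: float
    p_low: float
    n_perm: int
    classification: str


def shuffle_tip_labels(D: DistanceMatrix, rng: np.random.Generator) -> DistanceMatrix:
    """Return D with taxon labels permuted uniformly at random.

    The off-diagonal value multiset is conserved; only the label-to-row
    mapping changes.
    """
    n = D.shape[0]
    perm = rng.permutation(n)
    return DistanceMatrix(D.data[np.ix_(perm, perm)], ids=list(D.ids))


def _classify(p_high: float, p_low: float, sd: float, alpha: float) -> str:
    if sd == 0:
        return "undefined"
    if p_high < alpha:
        return "overdispersed"
    if p_low < alpha:
        return "underdispersed"
    return "random"


def ses(observed: float, null_values, alpha: float = 0.025, target=None, ) -> SESResult:
    """Standardized effect size of one observed value against its null
    distribution.  Ties count toward both tails; the observed value is
    not added to the null set."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if null.size < 2:
        raise ValueError("need at least two null values for a standard deviation")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    # a numerically-zero null spread (e.g. monospecific plots, identical
    # compositions) counts as degenerate, not as a huge effect size
    if sd <= 1e-12 * max(1.0, abs(mean), abs(observed)):
        sd = 0.0
    p_high = float(np.mean(null >= observed))
    p_low = float(np.mean(null <= observed))
    val = (observed - mean) / sd if sd > 0 else float("nan")
    return SESResult(
        target=target,
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=val,
        p_high=p_high,
        p_low=p_low,
        n_perm=int(null.size),
        classification=_classify(p_high, p_low, sd, alpha),
    )


def _prep_groups(groups: dict, regional_D: DistanceMatrix, corrected: bool):
    """Align every group's count table to the regional label order and
    rescale distances once if corrected."""
    labels = list(regional_D.ids)
    dvals = regional_D.data.astype(float)
    if corrected:
        dmax = dvals.max()
        if dmax > 0:
            dvals = dvals / dmax
    mats = {}
    for name, cm in groups.items():
        missing = sorted(set(cm.columns) - set(labels))
        if missing:
            raise ValueError(
                f"group {name!r}: species missing from regional distance "
                f"matrix: {missing}"
            )
        full = pd.DataFrame(0.0, index=cm.index, columns=labels)
        full.loc[:, list(cm.columns)] = cm.to_numpy(dtype=float)
        mats[name] = full
    return mats, dvals


def _alpha_values(P: np.ndarray, dvals: np.ndarray, corrected: bool) -> np.ndarray:
    q = _rao_rows(P, dvals)
    if corrected:
        return 1.0 / (1.0 - q)
    return q


def _results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "group", "target", "observed", "null_mean", "null_sd",
            "ses", "p_high", "p_low", "n_perm", "classification",
        ],
    )


def _null_loop(mats, dvals, n_perm, rng, shared_shuffle, per_group_stat):
    """Run the tip-shuffle loop.

    ``per_group_stat(name, P_full, dvals)`` returns the statistic vector
    for one group given an aligned plots x regional-species matrix.
    Returns dict name -> (observed vector, null matrix n_perm x k).
    """
    S = dvals.shape[0]
    observed = {}
    Ps = {}
    for name, full in mats.items():
        counts = full.to_numpy(dtype=float)
        P = counts / counts.sum(axis=1, keepdims=True)
        Ps[name] = P
        observed[name] = per_group_stat(name, P, dvals)
    nulls = {name: np.empty((n_perm, len(obs))) for name, obs in observed.items()}
    names = list(mats)
    for it in range(n_perm):
        if shared_shuffle:
            perms = {name: None for name in names}
            perm = rng.permutation(S)
            for name in names:
                perms[name] = perm
        else:
            perms = {name: rng.permutation(S) for name in names}
        for name in names:
            perm = perms[name]
            Pp = Ps[name][:, perm]
            nulls[name][it] = per_group_stat(name, Pp, dvals)
    return observed, nulls


def alpha_pd_ses(
    groups: dict,
    regional_D: DistanceMatrix,
    n_perm: int = 3000,
    alpha: float = 0.025,
    rng: np.random.Generator | int | None = None,
    corrected: bool = True,
    shared_shuffle: bool = True,
) -> pd.DataFrame:
    """SES of per-plot alpha diversity against the tip-shuffle null.

    ``groups`` maps group names (life stages / taxa) to plots x species
    count tables; all species must appear in ``regional_D`` (the
    regional pool).  Returns a long-form DataFrame of SESResult fields.
    """
    rng = np.random.default_rng(rng)
    mats, dvals = _prep_groups(groups, regional_D, corrected)

    def stat(name, P, dv):
        return _alpha_values(P, dv, corrected)

    observed, nulls = _null_loop(mats, dvals, n_perm, rng, shared_shuffle, stat)
    rows = []
    for name, full in mats.items():
        for k, plot in enumerate(full.index):
            r = ses(observed[name][k], nulls[name][:, k], alpha=alpha, target=plot)
            rows.append((name, plot, r.observed, r.null_mean, r.null_sd,
                         r.ses, r.p_high, r.p_low, r.n_perm, r.classification))
    return _results_frame(rows)


def beta_pd_ses(
    groups: dict,
    regional_D: DistanceMatrix,
    n_perm: int = 3000,
    alpha: float = 0.025,
    rng: np.random.Generator | int | None = None,
    corrected: bool = True,
    shared_shuffle: bool = True,
    pooling: str = "counts",
) -> pd.DataFrame:
    """SES of pairwise multiplicative beta against the tip-shuffle null."""
    rng = np.random.default_rng(rng)
    mats, dvals = _prep_groups(groups, regional_D, corrected)
    pair_idx = {}
    for name, full in mats.items():
        n = full.shape[0]
        if n < 2:
            raise ValueError(f"group {name!r}: need >= 2 plots for beta SES")
        pair_idx[name] = np.triu_indices(n, k=1)

    def pooled_from_rows(P, ii, jj, full):
        # pooled relative abundances are fixed convex combinations of the
        # two plot rows, so a column permutation of P carries over directly
        counts = full.to_numpy(dtype=float)
        tot = counts.sum(axis=1)
        if pooling == "counts":
            wi = (tot[ii] / (tot[ii] + tot[jj]))[:, None]
            return wi * P[ii] + (1 - wi) * P[jj]
        return (P[ii] + P[jj]) / 2.0

    def stat(name, P, dv):
        ii, jj = pair_idx[name]
        alpha_v = _rao_rows(P, dv)
        pooled = pooled_from_rows(P, ii, jj, mats[name])
        gamma_v = _rao_rows(pooled, dv)
        return beta_from_components(gamma_v, alpha_v[ii], alpha_v[jj], corrected)

    observed, nulls = _null_loop(mats, dvals, n_perm, rng, shared_shuffle, stat)
    rows = []
    for name, full in mats.items():
        ii, jj = pair_idx[name]
        plots = list(full.index)
        for k in range(len(ii)):
            pair = (plots[ii[k]], plots[jj[k]])
            r = ses(observed[name][k], nulls[name][:, k], alpha=alpha, target=pair)
            rows.append((name, pair, r.observed, r.null_mean, r.null_sd,
                         r.ses, r.p_high, r.p_low, r.n_perm, r.classification))
    return _results_frame(rows)


def mpd_ses(
    groups: dict,
    regional_D: DistanceMatrix,
    n_perm: int = 999,
    alpha: float = 0.025,
    rng: np.random.Generator | int | None = None,
    shared_shuffle: bool = True,
) -> pd.DataFrame:
    """SES of abundance-weighted mean pairwise distance (the robustness
    alternative to Rao alpha-PD; 999 permutations by default)."""
    rng = np.random.default_rng(rng)
    mats, dvals = _prep_groups(groups, regional_D, corrected=False)

    def stat(name, P, dv):
        num = _rao_rows(P, dv)
        den = 1.0 - (P**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    observed, nulls = _null_loop(mats, dvals, n_perm, rng, shared_shuffle, stat)
    rows = []
    for name, full in mats.items():
        for k, plot in enumerate(full.index):
            r = ses(observed[name][k], nulls[name][:, k], alpha=alpha, target=plot)
            rows.append((name, plot, r.observed, r.null_mean, r.null_sd,
                         r.ses, r.p_high, r.p_low, r.n_perm, r.classification))
    return _results_frame(rows)


def dispersion_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Tabulate dispersion classifications per group."""
    if len(results) == 0:
        return pd.DataFrame(columns=list(CLASSIFICATIONS))
    counts = (
        results.groupby("group")["classification"]
        .value_counts()
        .unstack(fill_value=0)
    )
    for c in CLASSIFICATIONS:
        if c not in counts.columns:
            counts[c] = 0
    return counts[list(CLASSIFICATIONS)]
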