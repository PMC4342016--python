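"""Multimodel inference for alpha-diversity regressions.

The global models are a linear mixed model with a plot random intercept
(plants, three life stages per plot) and an ordinary multiple regression
(birds), both fitted by maximum likelihood so AICc values are
comparable.  All predictor subsets respecting marginality (an
interaction is only included alongside both its main effects) are
enumerated ("dredging"), models with dAICc < 2.0 from the best model are
averaged with Akaike weights w_m proportional to exp(-d_m / 2), and each
term's importance is its summed weight over the retained models
containing it.

Averaging is conditional (subset) averaging by default: a coefficient is
averaged only over the models in which it appears.  The unconditional
standard error follows Burnham & Anderson,
sqrt(sum_m w_m (se_m^2 + (theta_m - theta_bar)^2)); the "adjusted" SE
additionally inflates each within-model variance by df_m / (df_m - 2)
(df_m = n - number of fixed effects) as a small-sample correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelSpec",
    "FittedModel",
    "AveragedModel",
    "ModelFitError",
    "z_transform",
    "fit_model",
    "aicc",
    "dredge",
    "average_models",
]


class ModelFitError(RuntimeError):
    """Raised when a model cannot be fitted (singular design,
    non-convergence)."""


@dataclass
class ModelSpec:
    response: str
    fixed_terms: list
    data: pd.DataFrame
    random_intercept: str | None = None

    def formula(self, terms=None) -> str:
        terms = self.fixed_terms if terms is None else list(terms)
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class FittedModel:
    terms: tuple
    formula: str
    params: pd.Series
    bse: pd.Series
    llf: float
    k: int
    n: int
    aicc: float
    n_fixed: int
    random_intercept: str | None = None


@dataclass
class AveragedModel:
    table: pd.DataFrame            # per-coefficient estimate/SEs/z/p
    importance: pd.Series          # per-term summed Akaike weights
    model_set: pd.DataFrame        # retained models with weights
    method: str = "conditional"
    dropped: list = field(default_factory=list)


def z_transform(column) -> pd.Series:
    """Center and scale to unit (sample) standard deviation."""
    x = pd.Series(column, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot Z-transform a constant column")
    return (x - x.mean()) / sd


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion
    2k - 2 logL + 2k(k+1)/(n - k - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return 2 * k - 2 * log_likelihood + 2 * k * (k + 1) / (n - k - 1)


def _check_marginality(terms) -> None:
    tset = set(terms)
    for t in terms:
        if ":" in t:
            for parent in t.split(":"):
                if parent not in tset:
                    raise ValueError(
                        f"interaction {t!r} present without main effect "
                        f"{parent!r}"
                    )


def fit_model(spec: ModelSpec, terms=None) -> FittedModel:
    """Maximum-likelihood fit of one member model.

    With a random intercept a linear mixed model is fitted (ML, not
    REML); otherwise ordinary least squares.  The parameter count k
    includes the residual variance and, when present, the
    random-intercept variance.
    """
    terms = tuple(spec.fixed_terms if terms is None else terms)
    _check_marginality(terms)
    formula = spec.formula(terms)
    data = spec.data
    if spec.random_intercept is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data,
                                groups=data[spec.random_intercept])
            _check_rank(model.exog, model.exog_names)
            res = None
            # the ML surface is flat when the intercept variance shrinks
            # to zero; fall through a few optimizers before declaring the
            # boundary fit
            for method in (["lbfgs"], ["powell"], ["cg"], ["nm"]):
                try:
                    res = model.fit(reml=False, method=method)
                except ModelFitError:
                    raise
                except Exception:
                    res = None
                    continue
                if res.converged:
                    break
        if res is not None and res.converged:
            params = res.fe_params
            bse = res.bse_fe
            llf = float(res.llf)
        else:
            # random-intercept variance at the boundary (zero): the ML fit
            # coincides with OLS; the variance component still counts in k
            try:
                ols = smf.ols(formula, data).fit()
            except Exception as exc:
                raise ModelFitError(f"{formula}: {exc}") from exc
            params = ols.params
            bse = ols.bse
            llf = float(ols.llf)
        n_fixed = len(params)
        k = n_fixed + 2  # residual variance + random-intercept variance
        n = int(model.nobs)
    else:
        try:
            model = smf.ols(formula, data)
            _check_rank(model.exog, model.exog_names)
            res = model.fit()
        except ModelFitError:
            raise
        except Exception as exc:
            raise ModelFitError(f"{formula}: {exc}") from exc
        params = res.params
        bse = res.bse
        llf = float(res.llf)
        n_fixed = len(params)
        k = n_fixed + 1  # residual variance
        n = int(res.nobs)
    return FittedModel(
        terms=terms,
        formula=formula,
        params=params,
        bse=bse,
        llf=llf,
        k=k,
        n=n,
        aicc=aicc(llf, k, n),
        n_fixed=n_fixed,
        random_intercept=spec.random_intercept,
    )


def _check_rank(exog, names) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ModelFitError(
            f"singular fixed-effect design (rank {rank} < {exog.shape[1]}; "
            f"columns {list(names)})"
        )


def admissible_subsets(terms) -> list:
    """All subsets of *terms* respecting marginality, including the
    empty (intercept-only) subset, in enumeration order."""
    terms = list(terms)
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            cset = set(combo)
            ok = all(
                all(p in cset for p in t.split(":"))
                for t in combo if ":" in t
            )
            if ok:
                out.append(tuple(combo))
    return out


def dredge(spec: ModelSpec) -> list:
    """Fit every admissible predictor subset of the global model.

    Member-fit failures are recorded as warnings and the member excluded.
    Returns fitted models sorted by AICc (best first).
    """
    fitted = []
    for combo in admissible_subsets(spec.fixed_terms):
        try:
            fitted.append(fit_model(spec, combo))
        except ModelFitError as exc:
            warnings.warn(f"dropping model: {exc}", stacklevel=2)
    if not fitted:
        raise ModelFitError("no member model could be fitted")
    fitted.sort(key=lambda m: m.aicc)
    return fitted


def _coef_term_map(model: FittedModel) -> dict:
    """Map each fitted coefficient name to the formula term producing it."""
    mapping = {}
    for name in model.params.index:
        if name in ("Intercept", "const"):
            mapping[name] = "Intercept"
            continue
        # categorical expansions look like C(stage)[T.sapling] or
        # C(stage)[T.sapling]:x; strip the level part to recover the term
        term = name
        while "[" in term:
            lo = term.index("[")
            hi = term.index("]", lo)
            term = term[:lo] + term[hi + 1:]
        mapping[name] = term
    return mapping


def average_models(
    models: list,
    delta: float = 2.0,
    method: str = "conditional",
) -> AveragedModel:
    """Akaike-weight model averaging over the dAICc < *delta* set.

    ``method='conditional'`` averages each coefficient over the models
    containing it (weights renormalized); ``method='full'`` substitutes
    zero in models lacking the coefficient.
    """
    if not models:
        raise ValueError("no models to average")
    if method not in ("conditional", "full"):
        raise ValueError(f"unknown averaging method {method!r}")
    best = min(m.aicc for m in models)
    retained = [m for m in models if m.aicc - best < delta]
    deltas = np.array([m.aicc - best for m in retained])
    w = np.exp(-deltas / 2.0)
    w = w / w.sum()

    model_set = pd.DataFrame(
        {
            "formula": [m.formula for m in retained],
            "llf": [m.llf for m in retained],
            "k": [m.k for m in retained],
            "n": [m.n for m in retained],
            "aicc": [m.aicc for m in retained],
            "delta": deltas,
            "weight": w,
        }
    )

    coef_names: list = []
    for m in retained:
        for name in m.params.index:
            if name not in coef_names:
                coef_names.append(name)

    rows = []
    for name in coef_names:
        present = np.array([name in m.params.index for m in retained])
        est = np.array(
            [m.params.get(name, 0.0) for m in retained], dtype=float
        )
        se = np.array([m.bse.get(name, 0.0) for m in retained], dtype=float)
        dfs = np.array([m.n - m.n_fixed for m in retained], dtype=float)
        if method == "conditional":
            wm = w[present] / w[present].sum()
            est_m, se_m, df_m = est[present], se[present], dfs[present]
        else:
            wm, est_m, se_m, df_m = w, est, se, dfs
        theta = float(np.sum(wm * est_m))
        dev2 = (est_m - theta) ** 2
        unc_se = float(np.sqrt(np.sum(wm * (se_m**2 + dev2))))
        infl = np.where(df_m > 2, df_m / (df_m - 2.0), 1.0)
        adj_se = float(np.sqrt(np.sum(wm * (se_m**2 * infl + dev2))))
        zval = theta / adj_se if adj_se > 0 else np.nan
        pval = 2 * stats.norm.sf(abs(zval)) if np.isfinite(zval) else np.nan
        rows.append((name, theta, unc_se, adj_se, zval, pval))
    table = pd.DataFrame(
        rows, columns=["coefficient", "estimate", "se", "adjusted_se", "z", "p"]
    ).set_index("coefficient")

    all_terms: list = []
    for m in retained:
        for t in m.terms:
            if t not in all_terms:
                all_terms.append(t)
    importance = pd.Series(
        {
            t: float(w[[t in m.terms for m in retained]].sum())
            for t in all_terms
        },
        name="akaike_weight",
    )
    return AveragedModel(
        table=table, importance=importance, model_set=model_set, method=method
    )
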