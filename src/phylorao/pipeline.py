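"""End-to-end orchestration of the diversity analysis on a dataset bundle.

A bundle (in memory from :func:`phylorao.synthetic_data.simulate_dataset`
or on disk from :func:`load_bundle`) holds trees, per-group community
tables and the plot environment table.  The stages are:

1. regional patristic distance matrices (plant tree pruned to the union
   of species observed in any life stage; bird tree to observed birds);
2. alpha diversity: corrected Rao taxonomic alpha, and phylogenetic
   alpha standardized against the tip-shuffle null (alpha-PD SES);
3. environmental PCA defining the disturbance (PC1) and loss (PC2) axes;
4. AICc dredging and model averaging of the alpha regressions — a mixed
   model with plot random intercept across plant life stages, an OLS for
   birds;
5. beta diversity: partial Mantel tests of beta against gradient
   distances conditioned on space, and PCNM + forward selection +
   variation partitioning;
6. an optional sweep over a posterior sample of trees to propagate
   phylogenetic uncertainty.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, environment, models, nullmodels, phylo_io, spatial

logger = logging.getLogger(__name__)

__all__ = [
    "load_bundle",
    "regional_distance",
    "observed_table",
    "run_alpha",
    "run_beta",
    "posterior_sweep",
]

PLANT_STAGES = ("adult", "sapling", "seedling")


def load_bundle(path) -> dict:
    """Load an on-disk fixture bundle written by
    :func:`phylorao.synthetic_data.make_fixture`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    bundle = {
        "manifest": manifest,
        "plant_tree": phylo_io.read_newick((path / "plant_tree.nwk").read_text()),
        "bird_tree": phylo_io.read_newick((path / "bird_tree.nwk").read_text()),
        "environment": pd.read_csv(path / "environment.csv", index_col=0),
        "truth": pd.read_csv(path / "truth.csv", index_col=0),
        "communities": {},
    }
    for f in manifest["files"]:
        if f.startswith("community_"):
            group = f[len("community_"):-len(".csv")]
            bundle["communities"][group] = diversity.read_community_csv(path / f)
    for key in ("plant_posterior", "bird_posterior"):
        f = path / f"{key}.nwk"
        if f.exists():
            bundle[key] = phylo_io.read_tree_set(f.read_text())
    return bundle


def observed_table(cm: pd.DataFrame) -> pd.DataFrame:
    """Restrict a count table to species observed in at least one plot."""
    return cm.loc[:, cm.sum(axis=0) > 0]


def regional_distance(tree, communities: dict):
    """Patristic distance matrix of the tree pruned to the union of
    species observed in any of the given groups (the regional pool)."""
    pool = set()
    for cm in communities.values():
        pool |= set(observed_table(cm).columns)
    pruned = phylo_io.prune_to_taxa(tree, pool)
    return phylo_io.patristic_distances(pruned)


def _predictor_table(env: pd.DataFrame) -> pd.DataFrame:
    axes, _ = environment.derive_axes(env)
    pred = axes.copy()
    pred["easting"] = env["easting"]
    pred["northing"] = env["northing"]
    return pred


def _z_predictors(pred: pd.DataFrame) -> pd.DataFrame:
    return pred.apply(models.z_transform)


PLANT_TERMS = [
    "C(life_stage)",
    "disturbance",
    "C(life_stage):disturbance",
    "loss",
    "easting",
    "northing",
]
BIRD_TERMS = ["disturbance", "loss", "easting", "northing"]


def _plant_long_table(values: dict, predictors: pd.DataFrame) -> pd.DataFrame:
    """Stack per-stage plot values into the long table for the mixed
    model (plot, life_stage, response + Z-scored predictors)."""
    rows = []
    for stage, series in values.items():
        df = pd.DataFrame({"response": series})
        df["life_stage"] = stage
        df["plot"] = list(df.index)
        rows.append(df.reset_index(drop=True))
    long = pd.concat(rows, axis=0, ignore_index=True)
    long = long.join(predictors, on="plot")
    long = long.dropna(subset=["response"])
    # reference level = adult trees
    long["life_stage"] = pd.Categorical(
        long["life_stage"],
        categories=[s for s in PLANT_STAGES if s in values] +
                   [s for s in values if s not in PLANT_STAGES],
    )
    return long.reset_index(drop=True)


def run_alpha(
    bundle: dict,
    n_perm: int = 3000,
    alpha: float = 0.025,
    delta: float = 2.0,
    seed: int | None = None,
    corrected: bool = True,
) -> dict:
    """Alpha-diversity analysis: SES computation, dredging, averaging.

    Returns a dict with the per-plot alpha values, the SES table with
    dispersion classifications, and one averaged-model report per
    response (plant/bird x TD/PD).
    """
    rng = np.random.default_rng(seed)
    comms = {g: observed_table(cm) for g, cm in bundle["communities"].items()}
    plant_groups = {g: comms[g] for g in comms if g in PLANT_STAGES}
    plant_D = regional_distance(bundle["plant_tree"], plant_groups)
    bird_D = regional_distance(bundle["bird_tree"], {"bird": comms["bird"]})

    # taxonomic alpha (corrected Rao = inverse Gini-Simpson)
    td = {}
    for g, cm in comms.items():
        D_tax = diversity.taxonomic_distances(list(cm.columns))
        td[g] = diversity.alpha_profile(cm, D_tax, corrected=True)["corrected"]

    ses_plants = nullmodels.alpha_pd_ses(
        plant_groups, plant_D, n_perm=n_perm, alpha=alpha,
        rng=rng, corrected=corrected,
    )
    ses_birds = nullmodels.alpha_pd_ses(
        {"bird": comms["bird"]}, bird_D, n_perm=n_perm, alpha=alpha,
        rng=rng, corrected=corrected,
    )
    ses_table = pd.concat([ses_plants, ses_birds], ignore_index=True)
    n_undef = int((ses_table["classification"] == "undefined").sum())
    if n_undef:
        logger.warning("%d plot(s) with undefined SES dropped from models",
                       n_undef)

    pd_values = {}
    for g in list(plant_groups) + ["bird"]:
        sub = ses_table[ses_table["group"] == g].set_index("target")
        pd_values[g] = sub["ses"]

    predictors = _z_predictors(_predictor_table(bundle["environment"]))

    reports = {}
    # plants: mixed model across life stages
    for facet, values in (("td", td), ("pd", pd_values)):
        plant_vals = {g: values[g] for g in plant_groups}
        long = _plant_long_table(plant_vals, predictors)
        spec = models.ModelSpec(
            response="response",
            fixed_terms=list(PLANT_TERMS),
            data=long,
            random_intercept="plot",
        )
        fitted = models.dredge(spec)
        reports[f"plant_{facet}"] = models.average_models(fitted, delta=delta)
        # birds: multiple linear regression
        bird_df = pd.DataFrame({"response": values["bird"]}).join(predictors)
        bird_df = bird_df.dropna(subset=["response"])
        spec_b = models.ModelSpec(
            response="response",
            fixed_terms=list(BIRD_TERMS),
            data=bird_df.reset_index(drop=True),
        )
        fitted_b = models.dredge(spec_b)
        reports[f"bird_{facet}"] = models.average_models(fitted_b, delta=delta)

    return {
        "alpha_td": td,
        "ses": ses_table,
        "dispersion": nullmodels.dispersion_summary(ses_table),
        "reports": reports,
        "predictors": predictors,
    }


def _ses_matrix(ses_df: pd.DataFrame, plots) -> np.ndarray:
    """Symmetric matrix of pairwise beta SES values (NaN -> 0, flagged)."""
    n = len(plots)
    idx = {p: i for i, p in enumerate(plots)}
    mat = np.zeros((n, n))
    for _, row in ses_df.iterrows():
        i, j = idx[row["target"][0]], idx[row["target"][1]]
        v = row["ses"]
        if not np.isfinite(v):
            v = 0.0
        mat[i, j] = mat[j, i] = v
    return mat


def _shift_nonnegative(mat: np.ndarray) -> np.ndarray:
    """Shift a symmetric score matrix so off-diagonal values are >= 0
    (needed to treat beta-PD SES as a dissimilarity for db-RDA)."""
    n = mat.shape[0]
    off = mat[np.triu_indices(n, 1)]
    lo = off.min() if off.size else 0.0
    if lo >= 0:
        return mat
    out = mat - lo
    np.fill_diagonal(out, 0.0)
    return out


def run_beta(
    bundle: dict,
    n_perm_mantel: int = 999,
    n_perm_ses: int = 1000,
    alpha_select: float = 0.050,
    seed: int | None = None,
    corrected: bool = True,
    groups: list | None = None,
) -> dict:
    """Beta-diversity analysis: partial Mantel tests (Table-2 layout) and
    PCNM + forward selection + variation partitioning (Fig-4 layout)."""
    rng = np.random.default_rng(seed)
    comms = {g: observed_table(cm) for g, cm in bundle["communities"].items()}
    if groups is None:
        groups = [g for g in comms if g in PLANT_STAGES] + (
            ["bird"] if "bird" in comms else []
        )
    plant_groups = {g: comms[g] for g in comms if g in PLANT_STAGES}
    plant_D = regional_distance(bundle["plant_tree"], plant_groups)
    bird_D = (
        regional_distance(bundle["bird_tree"], {"bird": comms["bird"]})
        if "bird" in comms else None
    )

    env = bundle["environment"]
    axes, _ = environment.derive_axes(env)
    plots = [str(p) for p in env.index]
    space_D = spatial.euclidean_plot_distances(env)
    dist_D = spatial.gradient_distance(axes["disturbance"])
    loss_D = spatial.gradient_distance(axes["loss"])
    pcnm = spatial.pcnm_basis(space_D)

    # beta-PD SES per group (shared null within plants)
    ses_pd = {}
    if plant_groups:
        df = nullmodels.beta_pd_ses(
            plant_groups, plant_D, n_perm=n_perm_ses, rng=rng,
            corrected=corrected,
        )
        for g in plant_groups:
            ses_pd[g] = df[df["group"] == g]
    if "bird" in comms:
        df = nullmodels.beta_pd_ses(
            {"bird": comms["bird"]}, bird_D, n_perm=n_perm_ses, rng=rng,
            corrected=corrected,
        )
        ses_pd["bird"] = df[df["group"] == "bird"]

    mantel_rows = []
    varpart = {}
    for g in groups:
        cm = comms[g]
        D_tax = diversity.taxonomic_distances(list(cm.columns))
        beta_td = diversity.pairwise_beta(cm, D_tax, corrected=corrected)
        mat_td = beta_td.matrix.data
        mat_pd = _ses_matrix(ses_pd[g], list(cm.index))
        for facet, mat in (("td", mat_td), ("pd", mat_pd)):
            for pred_name, pred_D in (("disturbance", dist_D),
                                      ("loss", loss_D)):
                r, p = spatial.partial_mantel(
                    mat, pred_D.data, space_D.data,
                    n_perm=n_perm_mantel, rng=rng,
                )
                mantel_rows.append((g, facet, pred_name, r, p))
            resp = mat if facet == "td" else _shift_nonnegative(mat)
            Y = spatial.pcoa_coordinates(resp)
            sel = spatial.forward_select(
                Y, pcnm.eigenvectors, alpha=alpha_select,
                n_perm=n_perm_mantel, rng=rng,
            )
            space_X = pcnm.eigenvectors[sel] if sel else None
            vp = spatial.variation_partition(
                resp, axes["disturbance"], axes["loss"], space_X,
                n_perm=n_perm_mantel, rng=rng,
            )
            varpart[(g, facet)] = {
                "selected_pcnm": sel,
                "partition": vp,
            }
    mantel_table = pd.DataFrame(
        mantel_rows, columns=["group", "facet", "predictor", "r", "p"]
    )
    return {
        "mantel": mantel_table,
        "varpart": varpart,
        "pcnm": pcnm,
        "beta_pd_ses": ses_pd,
    }


def posterior_sweep(
    bundle: dict,
    max_trees: int = 1000,
    n_perm: int = 200,
    n_perm_mantel: int = 199,
    seed: int | None = None,
    delta: float = 2.0,
) -> dict:
    """Repeat the plant alpha-PD model averaging and the beta-PD partial
    Mantel test over a posterior sample of trees.

    Reports per-tree averaged disturbance coefficients and Mantel
    statistics, their means/SDs, and how often each predictor entered
    the averaged model.
    """
    if "plant_posterior" not in bundle:
        raise ValueError("bundle has no plant posterior")
    posterior = bundle["plant_posterior"]
    trees = list(posterior)[:max_trees]
    if len(posterior) < max_trees:
        logger.warning("posterior holds %d < %d trees; using all",
                       len(posterior), max_trees)
    rng = np.random.default_rng(seed)
    comms = {g: observed_table(cm) for g, cm in bundle["communities"].items()}
    plant_groups = {g: comms[g] for g in comms if g in PLANT_STAGES}
    env = bundle["environment"]
    predictors = _z_predictors(_predictor_table(env))
    axes, _ = environment.derive_axes(env)
    space_D = spatial.euclidean_plot_distances(env)
    dist_D = spatial.gradient_distance(axes["disturbance"])

    coef_rows, mantel_rows, inclusion = [], [], {}
    n_failed = 0
    for t_idx, tree in enumerate(trees):
        try:
            D = regional_distance(tree, plant_groups)
            ses_df = nullmodels.alpha_pd_ses(
                plant_groups, D, n_perm=n_perm, rng=rng
            )
            values = {
                g: ses_df[ses_df["group"] == g].set_index("target")["ses"]
                for g in plant_groups
            }
            long = _plant_long_table(values, predictors)
            spec = models.ModelSpec(
                response="response", fixed_terms=list(PLANT_TERMS),
                data=long, random_intercept="plot",
            )
            avg = models.average_models(models.dredge(spec), delta=delta)
            for term, w in avg.importance.items():
                inclusion[term] = inclusion.get(term, 0) + 1
            est = avg.table["estimate"].get("disturbance", np.nan)
            pval = avg.table["p"].get("disturbance", np.nan)
            coef_rows.append((t_idx, est, pval))

            first = next(iter(plant_groups))
            beta_df = nullmodels.beta_pd_ses(
                {first: plant_groups[first]}, D, n_perm=n_perm, rng=rng,
            )
            mat = _ses_matrix(beta_df, list(plant_groups[first].index))
            r, p = spatial.partial_mantel(
                mat, dist_D.data, space_D.data,
                n_perm=n_perm_mantel, rng=rng,
            )
            mantel_rows.append((t_idx, r, p))
        except Exception as exc:  # member-run failures are tallied
            logger.warning("sweep member %d failed: %s", t_idx, exc)
            n_failed += 1
    coefs = pd.DataFrame(coef_rows, columns=["tree", "estimate", "p"])
    mant = pd.DataFrame(mantel_rows, columns=["tree", "r", "p"])
    return {
        "coefficients": coefs,
        "mantel": mant,
        "inclusion": pd.Series(inclusion, name="n_models"),
        "n_failed": n_failed,
        "summary": {
            "disturbance_estimate_mean": float(coefs["estimate"].mean()),
            "disturbance_estimate_sd": float(coefs["estimate"].std(ddof=1))
            if len(coefs) > 1 else 0.0,
            "mantel_r_mean": float(mant["r"].mean()),
            "mantel_p_mean": float(mant["p"].mean()),
        },
    }
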