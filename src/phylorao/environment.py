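"""Plot-level environmental predictors.

Forest-fragment characteristics (fragment geometry, vertical biomass
profile, canopy cover, light, vegetation heterogeneity, two binary
habitat dummies) are reduced by a PCA on the correlation matrix.  The
first two components are interpreted as environmental gradients: PC1 =
"forest disturbance" (oriented so that higher scores mean lower canopy
cover) and PC2 = "forest loss" (oriented so that higher scores mean
smaller fragments).  Broken-stick proportions give an advisory retention
count; the downstream models always use exactly these two axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ENV_VARIABLES",
    "BIOMASS_COLUMNS",
    "PCAResult",
    "shannon_heterogeneity",
    "pca_correlation",
    "broken_stick",
    "derive_axes",
]

BIOMASS_COLUMNS = [
    "biomass_0_0",
    "biomass_0_5",
    "biomass_1_0",
    "biomass_2_0",
    "biomass_4_0",
    "biomass_8_0",
    "biomass_16_0",
]

#: The environment-table columns entering the PCA, in canonical order.
ENV_VARIABLES = (
    ["forest_size", "edge_length", "perimeter_area_ratio"]
    + BIOMASS_COLUMNS
    + ["canopy_cover", "relative_light", "heterogeneity",
       "forest_type_dummy", "matrix_dummy"]
)


@dataclass
class PCAResult:
    loadings: pd.DataFrame      # variables x components (eigenvectors)
    explained: np.ndarray       # proportion of variance per component
    scores: pd.DataFrame        # plots x components
    retained: int               # broken-stick retention count


def shannon_heterogeneity(biomass_layers) -> float:
    """Shannon index (nats) of the biomass distribution across the seven
    vertical layers; zero-biomass layers contribute nothing."""
    b = np.asarray(biomass_layers, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass values must be non-negative")
    total = b.sum()
    if total == 0:
        raise ValueError("all biomass layers are zero")
    q = b[b > 0] / total
    return float(-(q * np.log(q)).sum())


def pca_correlation(X: pd.DataFrame) -> PCAResult:
    """PCA via eigen-decomposition of the correlation matrix.

    Columns are standardized, components ordered by decreasing
    eigenvalue; the sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    sd = X.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant columns: {constant}")
    Z = (X - X.mean()) / sd
    R = np.corrcoef(Z.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1
    explained = eigval / eigval.sum()
    comp_names = [f"PC{i+1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=comp_names)
    scores = pd.DataFrame(
        Z.to_numpy(dtype=float) @ eigvec, index=X.index, columns=comp_names
    )
    bs = broken_stick(len(eigval))
    retained = 0
    for k in range(len(eigval)):
        if explained[k] > bs[k]:
            retained += 1
        else:
            break
    return PCAResult(loadings=loadings, explained=explained,
                     scores=scores, retained=retained)


def broken_stick(n_vars: int) -> np.ndarray:
    """Broken-stick expected proportions b_k = (1/n) sum_{i=k}^{n} 1/i."""
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    inv = 1.0 / np.arange(1, n_vars + 1)
    return np.cumsum(inv[::-1])[::-1] / n_vars


def derive_axes(env: pd.DataFrame) -> tuple[pd.DataFrame, PCAResult]:
    """Run the correlation-matrix PCA on the environment table and return
    per-plot (disturbance, loss) scores.

    PC1 is flipped so the canopy-cover loading is negative (higher
    disturbance = more open canopy); PC2 is flipped so the forest-size
    loading is negative (higher loss = smaller fragments).
    """
    missing = sorted(set(ENV_VARIABLES) - set(env.columns))
    if missing:
        raise ValueError(f"environment table missing variables: {missing}")
    res = pca_correlation(env[ENV_VARIABLES])
    if res.loadings.loc["canopy_cover", "PC1"] > 0:
        res.loadings["PC1"] *= -1
        res.scores["PC1"] *= -1
    if res.loadings.loc["forest_size", "PC2"] > 0:
        res.loadings["PC2"] *= -1
        res.scores["PC2"] *= -1
    axes = pd.DataFrame(
        {"disturbance": res.scores["PC1"], "loss": res.scores["PC2"]},
        index=env.index,
    )
    return axes, res
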