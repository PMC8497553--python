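"""Dental topographic morphospace: trait transforms and correlation-matrix PCA.

Species-mean metrics are assembled into a ``species x {ariadne, ln_opcr,
rfi}`` matrix (OPCR is ln-transformed because patch counts are count data),
z-scored per variable, and decomposed by PCA on the correlation matrix.  The
first two components define the 2-D morphospace used by the disparity and
centroid analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["build_trait_matrix", "zscore", "PCSpace", "standardized_pca", "project"]

#: canonical variable order of the morphospace
VARIABLES = ("ariadne", "ln_opcr", "rfi")


def build_trait_matrix(species_means: pd.DataFrame) -> pd.DataFrame:
    """``{ariadne, opcr, rfi}`` species means -> ``{ariadne, ln_opcr, rfi}``."""
    out = pd.DataFrame(index=species_means.index)
    out["ariadne"] = species_means["ariadne"]
    out["ln_opcr"] = np.log(species_means["opcr"])
    out["rfi"] = species_means["rfi"]
    if out.isna().any().any():
        raise ValueError("trait matrix contains missing values")
    return out


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each column to mean 0, sd 1 (sample sd, ddof=1)."""
    sd = matrix.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s): {bad}")
    return (matrix - matrix.mean()) / sd


@dataclass
class PCSpace:
    """Fitted principal-component space over the three topographic variables."""

    loadings: pd.DataFrame  # variables x components, orthonormal columns
    explained_variance_ratio: np.ndarray  # non-increasing, sums to 1
    scores: pd.DataFrame  # species x components (fitting data)
    center: pd.Series  # per-variable mean of the fitting data
    scale: pd.Series  # per-variable sd (ddof=1) of the fitting data


def standardized_pca(matrix: pd.DataFrame) -> PCSpace:
    """PCA of the correlation matrix (equivalently, PCA of z-scored data).

    Sign convention: the RFI loading on PC1 and the ln-OPCR loading on PC2
    are forced non-negative, so downstream centroid paths are reproducible
    despite the inherent sign indeterminacy of eigenvectors.
    """
    if matrix.shape[0] < 4:
        raise ValueError("need at least 4 species for a stable PCA")
    z = zscore(matrix)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2 / (matrix.shape[0] - 1)
    evr = var / var.sum()
    loadings = vt.T  # variables x components
    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    load_df = pd.DataFrame(loadings, index=matrix.columns, columns=comp_names)
    # resolve signs
    for comp, anchor in (("PC1", "rfi"), ("PC2", "ln_opcr")):
        if comp in load_df.columns and anchor in load_df.index and load_df.loc[anchor, comp] < 0:
            load_df[comp] *= -1
    scores = pd.DataFrame(
        z.to_numpy() @ load_df.to_numpy(), index=matrix.index, columns=comp_names
    )
    return PCSpace(
        loadings=load_df,
        explained_variance_ratio=evr,
        scores=scores,
        center=matrix.mean(),
        scale=matrix.std(ddof=1),
    )


def project(matrix: pd.DataFrame, space: PCSpace, n_components: int = 2) -> pd.DataFrame:
    """Scores of (possibly new) species on the first ``n_components`` axes.

    Standardization uses the fitting data's center/scale, so projecting the
    fitting matrix reproduces ``space.scores`` and a species sitting at the
    variable means lands at the origin.
    """
    if list(matrix.columns) != list(space.loadings.index):
        raise ValueError(
            f"variable mismatch: {list(matrix.columns)} vs {list(space.loadings.index)}"
        )
    z = (matrix - space.center) / space.scale
    comps = space.loadings.columns[:n_components]
    return pd.DataFrame(
        z.to_numpy() @ space.loadings[comps].to_numpy(), index=matrix.index, columns=comps
    )
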