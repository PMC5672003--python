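"""Replicate-correlation maps and hierarchical clustering of elution profiles.

Two diagnostics on a profiling experiment: (1) the fraction-by-fraction
Pearson correlation between the two biological replicates — reproducible
separations put the maximal correlations on or next to the diagonal — and
(2) agglomerative clustering of the Gaussian-reconstructed, unit-max
normalized profiles, which groups co-eluting proteins.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .peakfit import PeakModel, gaussian_mixture

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ProfileMatrix:
    """Proteins x fractions intensity matrix for one replicate."""

    data: pd.DataFrame  # index: protein_id, columns: fraction ids
    normalization: str = "raw"  # raw | unit_max


def profiles_to_matrix(profiles) -> ProfileMatrix:
    """Stack ElutionProfiles of one replicate into a ProfileMatrix."""
    rows = {p.protein_id: p.intensities for p in profiles}
    cols = profiles[0].scheme.fraction_ids
    return ProfileMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=cols))


def normalize_unit_max(matrix: ProfileMatrix) -> ProfileMatrix:
    """Divide each row by its maximum; all-zero rows are dropped (logged)."""
    data = matrix.data
    maxima = data.max(axis=1)
    zero = maxima == 0
    if zero.any():
        log.debug("dropping %d all-zero rows before normalization", int(zero.sum()))
        data = data.loc[~zero]
        maxima = maxima.loc[~zero]
    return ProfileMatrix(data.div(maxima, axis=0), normalization="unit_max")


def fraction_correlation(
    matrix_rep1: ProfileMatrix, matrix_rep2: ProfileMatrix
) -> pd.DataFrame:
    """Fractions x fractions Pearson matrix between two replicates.

    Entry (i, j) correlates, over the shared proteins, replicate 1's fraction
    i with replicate 2's fraction j.  Fractions with zero variance yield NaN.
    """
    shared = matrix_rep1.data.index.intersection(matrix_rep2.data.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared proteins")
    x1 = matrix_rep1.data.loc[shared].to_numpy(dtype=float)
    x2 = matrix_rep2.data.loc[shared].to_numpy(dtype=float)
    if x1.shape[1] != x2.shape[1]:
        raise ValueError("replicates have different fraction counts")

    def _standardize(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / sd
        z[:, sd == 0] = np.nan
        return z

    z1, z2 = _standardize(x1), _standardize(x2)
    corr = z1.T @ z2 / len(shared)
    return pd.DataFrame(
        corr, index=matrix_rep1.data.columns, columns=matrix_rep2.data.columns
    )


def reconstruct_profiles(
    models: Sequence[PeakModel], fraction_ids: Sequence[int]
) -> ProfileMatrix:
    """Evaluate each model's accepted Gaussian peaks on the fraction grid."""
    grid = np.asarray(fraction_ids, dtype=float)
    rows = {}
    for m in models:
        params: list[float] = []
        for p in m.peaks:
            params += [p.amplitude, p.center, p.sigma]
        rows[m.protein_id] = gaussian_mixture(grid, *params) if params else np.zeros_like(grid)
    return ProfileMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=list(fraction_ids)))


def cluster_profiles(matrix: ProfileMatrix) -> tuple[list[str], np.ndarray]:
    """Average-linkage agglomerative clustering with 1 - Pearson distance.

    Expects unit-max normalized reconstructed profiles.  Returns the leaf
    order (protein ids) and the SciPy linkage matrix; both are deterministic
    and invariant (up to labels) under row permutation.
    """
    if matrix.normalization != "unit_max":
        raise ValueError("cluster_profiles expects a unit_max-normalized matrix")
    data = matrix.data.sort_index()  # row order independent of input order
    dist = pdist(data.to_numpy(dtype=float), metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    linkage = hierarchy.linkage(dist, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return [data.index[i] for i in leaves], linkage


def linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Render a SciPy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def _recurse(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = _recurse(node.get_left(), node.dist)
        right = _recurse(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return _recurse(tree, tree.dist) + ";"
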