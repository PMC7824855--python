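"""Sample-level PCA maps of expression matrices.

The map places each sample on the first two principal axes of the
samples x log2(FPKM + pseudocount) matrix after gene-wise centering
(no unit-variance scaling by default, so high-expression genes keep
their weight). Axis signs are fixed deterministically by making the
largest-magnitude gene loading on each axis positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OrdinationResult:
    """PCA coordinates and explained-variance fractions.

    coordinates
        Indexed by sample id with columns ``pc1``, ``pc2``.
    explained_variance_ratio
        Fraction of total variance on each reported axis (nonincreasing,
        in [0, 1]).
    loadings
        Genes x axes matrix of gene loadings.
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca_map(
    fpkm: pd.DataFrame,
    pseudocount: float = 1.0,
    scale: bool = False,
    n_components: int = 2,
) -> OrdinationResult:
    """Principal-component map of the samples of an FPKM matrix.

    Parameters
    ----------
    fpkm
        Genes x samples matrix of nonnegative abundances.
    pseudocount
        Added before the log2 transform.
    scale
        Also divide each gene by its standard deviation (genes with zero
        variance are left centered only).
    n_components
        Number of axes to report (default 2). Axes beyond the matrix rank
        carry zero coordinates and zero explained variance.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    n_genes, n_samples = fpkm.shape
    if n_samples < 3:
        raise ValueError(f"PCA map needs >= 3 samples, got {n_samples}")
    if n_genes < 2:
        raise ValueError(f"PCA map needs >= 2 genes, got {n_genes}")

    x = np.log2(fpkm.to_numpy(dtype=float).T + pseudocount)  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        nz = sd > 0
        x[:, nz] = x[:, nz] / sd[nz]

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    # deterministic sign: largest-|loading| gene positive on each axis
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0

    total_var = float((s**2).sum())
    if total_var == 0:
        raise ValueError("matrix has no variance across samples")
    coords = np.zeros((n_samples, n_components))
    coords[:, :k] = u[:, :k] * s[:k]
    evr = np.zeros(n_components)
    evr[:k] = (s[:k] ** 2) / total_var
    load = np.zeros((n_genes, n_components))
    load[:, :k] = vt[:k].T

    axis_names = [f"pc{i + 1}" for i in range(n_components)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=fpkm.columns, columns=axis_names),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(load, index=fpkm.index, columns=axis_names),
    )


def genotype_mean_coordinates(
    result: OrdinationResult, sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Mean PC coordinates per genotype (for cluster-distance summaries)."""
    coords = result.coordinates.join(sample_sheet["genotype"])
    return coords.groupby("genotype").mean()


def genotype_distance(means: pd.DataFrame, a: str, b: str) -> float:
    """Euclidean distance between two genotypes' mean coordinates."""
    return float(np.linalg.norm(means.loc[a] - means.loc[b]))
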