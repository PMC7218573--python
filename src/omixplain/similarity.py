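"""Sample-similarity structures: omics relationship matrices, Bray-Curtis
dissimilarities, and principal-coordinate ordination.

The relationship matrix of an omics layer is ``A = Z Z' / q`` where ``Z`` is
the n-by-q column-standardized feature matrix — the same construction used
for genomic relationship matrices in quantitative genetics, applied to
microbial taxa (M), functions (K), rumen metabolites (R) or serum
metabolites (S). Dividing by the feature count q makes A scale-free:
``trace(A) = n - 1`` for fully standardized columns, and the variance
attached to A in the mixed model is directly interpretable as the layer's
share of phenotypic variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables import FeatureTable, TableValidationError


@dataclass
class RelationshipMatrix:
    """n-by-n similarity matrix built from one standardized omics layer."""

    data: pd.DataFrame
    source_layer: str
    n_features_used: int

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.shape[0] != vals.shape[1] or list(self.data.index) != list(
            self.data.columns
        ):
            raise TableValidationError("relationship matrix must be square, id-labelled")
        if np.max(np.abs(vals - vals.T)) > 1e-10:
            raise TableValidationError("relationship matrix must be symmetric")
        eig = np.linalg.eigvalsh((vals + vals.T) / 2)
        if eig[0] < -1e-8 * max(eig[-1], 1e-300):
            raise TableValidationError("relationship matrix is not PSD within tolerance")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal dissimilarity matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.shape[0] != vals.shape[1] or list(self.data.index) != list(
            self.data.columns
        ):
            raise TableValidationError("distance matrix must be square, id-labelled")
        if np.max(np.abs(vals - vals.T)) > 1e-10:
            raise TableValidationError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(vals))) > 1e-12:
            raise TableValidationError("distance matrix must have a zero diagonal")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def build_relationship_matrix(z: FeatureTable) -> RelationshipMatrix:
    """Compute ``A = Z Z' / q`` from a z-scored layer."""
    if z.value_kind != "zscore":
        raise TableValidationError("relationship matrices are built from zscore tables")
    q = z.n_features
    if q == 0:
        raise TableValidationError("no features left to build a relationship matrix")
    Z = z.values
    A = Z @ Z.T / q
    A = (A + A.T) / 2
    return RelationshipMatrix(
        pd.DataFrame(A, index=z.data.index, columns=z.data.index),
        z.layer_kind,
        q,
    )


def bray_curtis(t: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between samples.

    A pair of samples with zero combined abundance has an undefined
    dissimilarity; it is reported as 0 with a warning.
    """
    vals = t.values
    if np.isnan(vals).any():
        raise TableValidationError("Bray-Curtis requires a table without NaN")
    if vals.min(initial=0.0) < 0:
        raise TableValidationError("Bray-Curtis requires non-negative values")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = squareform(pdist(vals, metric="braycurtis"))
    row_sums = vals.sum(axis=1)
    zero_pair = (row_sums[:, None] + row_sums[None, :]) == 0
    if np.any(zero_pair & ~np.eye(len(row_sums), dtype=bool)):
        warnings.warn(
            "sample pair(s) with zero combined abundance: distance set to 0",
            stacklevel=2,
        )
    d = np.where(zero_pair, 0.0, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(pd.DataFrame(d, index=t.data.index, columns=t.data.index))


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix ``-1/2 J D^2 J`` of a distance matrix."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d**2) @ j


@dataclass
class Ordination:
    coordinates: pd.DataFrame  # n x k
    eigenvalues: np.ndarray  # all n, descending, negatives clamped to 0
    proportion_explained: np.ndarray  # per kept axis


def pcoa(d: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical scaling (principal-coordinate analysis).

    Negative eigenvalues of the Gower-centered matrix (non-Euclidean input)
    are clamped to zero and excluded from the proportion-explained
    denominator; no Lingoes/Cailliez correction is applied.
    """
    n = len(d.sample_ids)
    if k > n - 1:
        raise ValueError("cannot extract more than n-1 principal coordinates")
    g = gower_center(d.values)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.min(initial=0.0) < -1e-12 * max(eigval.max(initial=0.0), 1.0):
        warnings.warn(
            "negative eigenvalues clamped to 0 (non-Euclidean distances)",
            stacklevel=2,
        )
    eigval = np.clip(eigval, 0.0, None)
    total = eigval.sum()
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    prop = eigval[:k] / total if total > 0 else np.zeros(k)
    return Ordination(
        pd.DataFrame(
            coords,
            index=d.data.index,
            columns=[f"PCo{i + 1}" for i in range(k)],
        ),
        eigval,
        prop,
    )
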