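"""Sample ordination: Euclidean distances and principal coordinate analysis.

Distances are computed between samples over the (normalised, filtered)
feature space of one block, or of two blocks row-concatenated. When blocks
with heterogeneous units are combined, each feature is standardised to unit
variance first so neither block dominates by scale. PCoA is classical
metric MDS: Gower double-centering of the squared distance matrix followed
by eigendecomposition; on truly Euclidean input it reproduces PCA of the
column-centred data up to axis sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import Block, OmicsMatrix, ValidationError


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    source_block: Block

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape must match sample ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        self.values = v


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray      # samples x k
    eigenvalues: np.ndarray      # non-increasing, length k
    variance_explained: np.ndarray  # fraction of positive-eigenvalue mass


def _feature_matrix(matrix: OmicsMatrix, standardize: bool) -> np.ndarray:
    x = matrix.values
    if standardize:
        sd = x.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0  # constant features contribute nothing either way
        x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return x


def euclidean_distances(matrix: OmicsMatrix,
                        second: OmicsMatrix | None = None,
                        standardize: bool | None = None) -> DistanceMatrix:
    """Pairwise sample Euclidean distances over one block or two combined.

    ``standardize`` controls per-feature unit-variance scaling before
    (concatenation and) distance computation; it defaults to True when two
    blocks are combined and False for a single block.
    """
    if second is None:
        if standardize is None:
            standardize = False
        x = _feature_matrix(matrix, standardize)
        block = matrix.block
    else:
        if list(matrix.sample_ids) != list(second.sample_ids):
            raise ValidationError(
                "combined blocks need identical sample sets in the same order"
            )
        if standardize is None:
            standardize = True
        x = np.vstack([_feature_matrix(matrix, standardize),
                       _feature_matrix(second, standardize)])
        block = Block.COMBINED
    d = squareform(pdist(x.T, metric="euclidean"))
    return DistanceMatrix(list(matrix.sample_ids), d, block)


def pcoa(d: DistanceMatrix, k: int | None = None,
         negative_tol: float = 1e-8) -> OrdinationResult:
    """Principal coordinate analysis (classical metric MDS).

    Double-centres -1/2 * J D^2 J, eigendecomposes, and returns the first
    ``k`` coordinates (default: all axes with positive eigenvalue) scaled
    by the square roots of their eigenvalues. Variance explained is each
    positive eigenvalue over the positive-eigenvalue total.
    """
    n = len(d.sample_ids)
    if k is not None and k > n - 1:
        raise ValidationError(f"k must be <= n-1 = {n - 1}, got {k}")
    d2 = d.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0  # symmetrise against round-off
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0)
    if eigval[-1] < -negative_tol * scale:
        warnings.warn(
            f"non-Euclidean input: most negative eigenvalue "
            f"{eigval[-1]:.3g} clipped to zero", stacklevel=2,
        )
    pos = np.clip(eigval, 0.0, None)
    n_pos = int((pos > negative_tol * scale).sum())
    if k is None:
        k = max(n_pos, 1)
    coords = eigvec[:, :k] * np.sqrt(pos[:k])[None, :]
    total = pos.sum()
    var = pos[:k] / total if total > 0 else np.zeros(k)
    return OrdinationResult(list(d.sample_ids), coords, eigval[:k], var)
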