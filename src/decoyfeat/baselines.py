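"""Linear and manifold baselines: PCA, Isomap, and two-stage t-SNE.

PCA is the reference featurization throughout: fit on the training
deviations, project/reconstruct, and score by reconstruction MSE under the
same squared-error convention as the autoencoders — the squared error of one
structure is SUMMED over all 3n coordinates, ||dS^ - dS||^2, and the MSE is
the mean of these sums over structures.  (Per-coordinate averaging is
available but off by default.)

Isomap and t-SNE are visualization/featurization baselines delegated to
scikit-learn; t-SNE is never applied to raw deviations directly but only
after a first-stage reduction (PCA or a trained encoder) to ``pre_dim``
dimensions, default 15, because of its quadratic cost in ambient dimension
handling and its tendency to degrade on very high-dimensional input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.manifold import TSNE, Isomap
from sklearn.neighbors import kneighbors_graph

from .errors import ConnectivityError, InvalidSpecError, ShapeError

__all__ = [
    "PCAModel",
    "EmbeddingResult",
    "pca_fit",
    "pca_project",
    "pca_reconstruct",
    "pca_mse",
    "isomap_embed",
    "tsne_visualize",
]


@dataclass
class PCAModel:
    """Top-k principal components of a training deviation matrix.

    ``components`` has orthonormal rows (k x 3n); ``eigenvalues`` are the
    corresponding covariance eigenvalues (Å², m-1 denominator), sorted
    descending.  The mean vector is retained: reference subtraction leaves
    column means near but not exactly zero.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]


@dataclass
class EmbeddingResult:
    """Latent coordinates of a set of structures, one row per structure."""

    codes: np.ndarray
    method: str
    provenance: dict = field(default_factory=dict)


def pca_fit(train: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA on the training deviation matrix.

    The decomposition is deterministic up to component sign.  Signs are
    fixed by orienting each component along the training-set mean (the mean
    displacement from the reference structure), which keeps independently
    fitted models of comparable ensembles commensurable; when a component is
    essentially orthogonal to the mean, the sign falls back to making the
    component's largest-magnitude entry positive.
    """
    X = np.asarray(train, dtype=float)
    if X.ndim != 2:
        raise ShapeError("training data must be a 2-D matrix")
    m, d = X.shape
    if not (1 <= k <= min(m, d)):
        raise InvalidSpecError(f"k={k} out of range for a {m} x {d} matrix")
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    components = Vt[:k].copy()
    eigenvalues = (s[:k] ** 2) / max(m - 1, 1)
    mean_norm = np.linalg.norm(mean)
    for row in components:
        along_mean = row @ mean
        if abs(along_mean) > 1e-6 * max(mean_norm, 1e-300):
            if along_mean < 0:
                row *= -1.0
        elif row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean=mean, components=components, eigenvalues=eigenvalues)


def _check_dim(model: PCAModel, data: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ShapeError(
            f"data dimension {X.shape[1]} does not match model dimension "
            f"{model.mean.shape[0]}"
        )
    return X


def pca_project(model: PCAModel, data: np.ndarray) -> np.ndarray:
    """Latent coordinates: (x - mean) @ components^T."""
    X = _check_dim(model, data)
    return (X - model.mean) @ model.components.T


def pca_reconstruct(model: PCAModel, codes: np.ndarray) -> np.ndarray:
    """Back-projection: codes @ components + mean."""
    codes = np.atleast_2d(np.asarray(codes, dtype=float))
    if codes.shape[1] != model.k:
        raise ShapeError(f"codes have {codes.shape[1]} columns, model has k={model.k}")
    return codes @ model.components + model.mean


def pca_mse(model: PCAModel, data: np.ndarray, per_coordinate: bool = False) -> float:
    """Mean reconstruction error of PCA on ``data`` (Å²).

    Squared error per structure is summed over all 3n coordinates; the MSE
    is the mean of these sums over structures.  With ``per_coordinate`` the
    sum is replaced by a mean over coordinates.
    """
    X = _check_dim(model, data)
    resid = X - pca_reconstruct(model, pca_project(model, X))
    per_structure = (resid**2).sum(axis=1)
    if per_coordinate:
        per_structure = per_structure / X.shape[1]
    return float(per_structure.mean())


def isomap_embed(data: np.ndarray, k_neighbors: int = 10, dim: int = 2) -> EmbeddingResult:
    """Geodesic-distance-preserving (Isomap) embedding of the deviations.

    Raises :class:`ConnectivityError` if the ``k_neighbors`` graph is
    disconnected (increase ``k_neighbors``).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ShapeError("data must be a 2-D matrix")
    graph = kneighbors_graph(X, n_neighbors=k_neighbors, mode="connectivity")
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp > 1:
        raise ConnectivityError(
            f"{k_neighbors}-neighbor graph has {n_comp} components; "
            "increase k_neighbors"
        )
    iso = Isomap(n_neighbors=k_neighbors, n_components=dim)
    codes = iso.fit_transform(X)
    return EmbeddingResult(
        codes=codes, method="isomap", provenance={"k_neighbors": k_neighbors, "dim": dim}
    )


def tsne_visualize(
    data: np.ndarray,
    pre_dim: int = 15,
    seed: int = 0,
    perplexity: float = 30.0,
    pre_reducer=None,
) -> EmbeddingResult:
    """Two-stage 2-D visualization: reduce to ``pre_dim`` first, then t-SNE.

    The first stage defaults to PCA; pass ``pre_reducer`` (a callable mapping
    the data matrix to an ``m x pre_dim`` matrix, e.g. a trained encoder) to
    use a learned featurization instead.  Stochastic, controlled by ``seed``.
    """
    X = np.asarray(data, dtype=float)
    if pre_dim < 2:
        raise InvalidSpecError("pre_dim must be at least 2")
    if pre_reducer is None:
        model = pca_fit(X, min(pre_dim, min(X.shape)))
        reduced = pca_project(model, X)
        first_stage = "pca"
    else:
        reduced = np.asarray(pre_reducer(X), dtype=float)
        first_stage = "custom"
    perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    )
    codes = tsne.fit_transform(reduced)
    return EmbeddingResult(
        codes=codes,
        method="tsne",
        provenance={"pre_dim": pre_dim, "seed": seed, "first_stage": first_stage},
    )
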